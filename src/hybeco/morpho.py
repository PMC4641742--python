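"""Landmark morphometrics: TPS I/O, generalized Procrustes, shape models.

Shapes are 21-landmark 2-D configurations. Generalized Procrustes analysis
(GPA) removes translation (centroid to origin), scale (unit centroid size)
and rotation (orthogonal Procrustes, rotations only — reflections are
corrected, all specimens digitised same-side). The aligned output is made
canonical by rotating the converged solution so the consensus principal
axes coincide with the coordinate axes, which pins the arbitrary global
orientation and makes alignment invariant to similarity transforms of any
input configuration.

Each of the 42 aligned coordinates is then modelled with the same
env x basis(size, m) x sp trait model used for the condition coefficient,
and deformation fields between conditions (or between observed hybrids and
their h-mixture expectation) are per-landmark displacement vectors with
per-coordinate Wald tests, multiplicity-adjusted across the 42 coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hybeco import condition as cond
from hybeco.genetics import CN, PT

N_LANDMARKS = 21


class AlignmentError(ValueError):
    pass


class TpsParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TPS format
# ---------------------------------------------------------------------------

def read_tps(
    path: str, expected_landmarks: int | None = N_LANDMARKS
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Parse a TPS file into {specimen id: (k, 2) array}.

    Handles LM=, coordinate pairs, ID=, IMAGE= and SCALE= records (scale is
    applied multiplicatively when present). Records whose landmark count
    differs from ``expected_landmarks`` are rejected individually; the
    second return value lists their report lines.
    """
    configs: dict[str, np.ndarray] = {}
    rejected: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()

    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(f"{path}:{i + 1}: expected LM=, got {line!r}")
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(f"{path}:{i + 1}: bad landmark count") from exc
        i += 1
        coords = []
        while len(coords) < n_lm:
            if i >= len(lines):
                raise TpsParseError(f"{path}: truncated record at EOF")
            parts = lines[i].split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"{path}:{i + 1}: expected 2 coordinates, got {lines[i]!r}"
                )
            coords.append([float(parts[0]), float(parts[1])])
            i += 1
        record_no += 1
        spec_id = f"specimen{record_no}"
        scale = None
        while i < len(lines):
            s = lines[i].strip()
            up = s.upper()
            if up.startswith("ID="):
                spec_id = s.split("=", 1)[1].strip()
                i += 1
            elif up.startswith("IMAGE="):
                img = s.split("=", 1)[1].strip()
                if spec_id == f"specimen{record_no}":
                    spec_id = img
                i += 1
            elif up.startswith("SCALE="):
                scale = float(s.split("=", 1)[1])
                i += 1
            elif not s:
                i += 1
            else:
                break
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        if not np.isfinite(arr).all():
            rejected.append(f"{spec_id}: non-finite coordinates")
            continue
        if expected_landmarks is not None and n_lm != expected_landmarks:
            rejected.append(
                f"{spec_id}: {n_lm} landmarks, expected {expected_landmarks}"
            )
            continue
        configs[spec_id] = arr
    return configs, rejected


def write_tps(configs: Mapping[str, np.ndarray], path: str) -> None:
    with open(path, "w") as fh:
        for spec_id, arr in configs.items():
            arr = np.asarray(arr, dtype=float)
            fh.write(f"LM={arr.shape[0]}\n")
            for x, y in arr:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={spec_id}\n")


# ---------------------------------------------------------------------------
# Procrustes machinery
# ---------------------------------------------------------------------------

def centroid_size(config: np.ndarray) -> float:
    centred = config - config.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def procrustes_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation (det +1) mapping ``source`` onto ``target``.

    Both inputs are assumed centred. Solved from the SVD of the 2x2
    cross-covariance; a reflection in the raw solution is corrected by
    flipping the smallest singular direction.
    """
    M = target.T @ source
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


@dataclass
class AlignedShape:
    specimen: str
    coords: np.ndarray
    centroid_size: float
    residual: float


@dataclass
class GPAResult:
    shapes: list[AlignedShape]
    consensus: np.ndarray
    iterations: int

    def coordinate_table(self) -> pd.DataFrame:
        """Wide table: one row per specimen, columns x1, y1, ..., x21, y21."""
        k = self.consensus.shape[0]
        cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
        rows = {
            s.specimen: s.coords.reshape(-1) for s in self.shapes
        }
        df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        df.index.name = "id"
        df["centroid_size"] = [s.centroid_size for s in self.shapes]
        return df.reset_index()


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation aligning the consensus principal axes with x/y.

    Sign convention: third moments of x then y are made positive using 180°
    rotations only, so the result is always a proper rotation.
    """
    _, _, Vt = np.linalg.svd(consensus - consensus.mean(axis=0))
    R = Vt.T
    if np.linalg.det(R) < 0:
        R[:, 1] = -R[:, 1]
    rot = consensus @ R
    if (rot[:, 0] ** 3).sum() < 0:
        R = R @ np.array([[-1.0, 0.0], [0.0, -1.0]])
        rot = consensus @ R
    return R


def gpa_align(
    configs: Mapping[str, np.ndarray],
    tol: float = 1e-12,
    max_iter: int = 500,
    scale: bool = True,
) -> GPAResult:
    """Iterative generalized Procrustes alignment.

    Translate centroids to the origin, scale to unit centroid size (full
    Procrustes; set ``scale=False`` for partial), rotate each configuration
    to the running consensus, update the consensus as the plain mean, and
    iterate to a fixed point. The converged set is rotated into canonical
    orientation (consensus principal axes on the coordinate axes).
    """
    ids = list(configs)
    if len(ids) < 2:
        raise AlignmentError("GPA needs at least 2 configurations")
    mats: list[np.ndarray] = []
    sizes: list[float] = []
    for spec_id in ids:
        arr = np.asarray(configs[spec_id], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
            raise AlignmentError(
                f"{spec_id}: expected (k>=3, 2) configuration, got {arr.shape}"
            )
        cs = centroid_size(arr)
        if cs < 1e-12:
            raise AlignmentError(f"{spec_id}: degenerate (coincident points)")
        centred = arr - arr.mean(axis=0)
        mats.append(centred / cs if scale else centred)
        sizes.append(cs)

    consensus = np.mean(mats, axis=0)
    if centroid_size(consensus) < 1e-9:  # scattered orientations
        consensus = mats[0].copy()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        aligned = [m @ procrustes_rotation(m, consensus).T for m in mats]
        new_consensus = np.mean(aligned, axis=0)
        change = np.abs(new_consensus - consensus).max()
        mats = aligned
        consensus = new_consensus
        if change < tol:
            break

    R = _canonical_rotation(consensus)
    consensus = consensus @ R
    mats = [m @ R for m in mats]

    shapes = [
        AlignedShape(
            specimen=spec_id,
            coords=m,
            centroid_size=cs,
            residual=float(np.sqrt(((m - consensus) ** 2).sum())),
        )
        for spec_id, m, cs in zip(ids, mats, sizes)
    ]
    return GPAResult(shapes=shapes, consensus=consensus, iterations=iterations)


# ---------------------------------------------------------------------------
# per-coordinate trait models
# ---------------------------------------------------------------------------

COORD_COLUMNS = [f"{ax}{i + 1}" for i in range(N_LANDMARKS) for ax in ("x", "y")]


@dataclass
class ShapeModelSet:
    """One trait-model fit per aligned coordinate."""

    fits: dict[str, cond.TraitModelFit]
    coord_columns: list[str]
    size_center: float

    def predict_shape(self, env: str, size: float, sp: str) -> np.ndarray:
        vals = [
            float(self.fits[c].predict([env], [size], [sp])[0])
            for c in self.coord_columns
        ]
        return np.asarray(vals).reshape(-1, 2)


def fit_shape_models(
    aligned: pd.DataFrame,
    covariates: pd.DataFrame,
    coord_columns: Sequence[str] | None = None,
    candidate_degrees: Sequence[int] = (1, 2, 3, 4, 5),
    basis: str = "poly",
) -> ShapeModelSet:
    """Model each aligned coordinate as env x basis(size, m) x sp.

    ``aligned`` is the wide coordinate table keyed by id; ``covariates``
    supplies env, sp and size_cm per id (pure specimens only). The AIC-
    selected degree is per coordinate.
    """
    df = aligned.merge(covariates, on="id", how="inner")
    if df.empty:
        raise cond.FitError("no overlap between aligned shapes and covariates")
    if coord_columns is None:
        coord_columns = [c for c in COORD_COLUMNS if c in aligned.columns]
    fits: dict[str, cond.TraitModelFit] = {}
    center = float(df["size_cm"].median())
    for c in coord_columns:
        try:
            fits[c] = cond.fit_trait_model(
                df, response=c, candidate_degrees=candidate_degrees,
                size_center=center, basis=basis, compute_type3=False,
            )
        except cond.FitError as exc:
            raise cond.FitError(f"coordinate {c}: {exc}") from exc
    return ShapeModelSet(
        fits=fits, coord_columns=list(coord_columns), size_center=center
    )


@dataclass
class DeformationField:
    """Per-landmark displacement between two predicted mean shapes."""

    landmarks: pd.DataFrame  # landmark, dx, dy, p_x, p_y, p_adj_x, p_adj_y,
                             # significant
    condition_a: dict
    condition_b: dict
    at_size: float
    warnings: list[str] = field(default_factory=list)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def deformation_between(
    models: ShapeModelSet,
    condition_a: dict,
    condition_b: dict,
    at_size: float,
    alpha: float = 0.05,
    adjust: str = "bh",
    size_range: tuple[float, float] | None = None,
) -> DeformationField:
    """Displacement field pred(B) - pred(A) with per-coordinate Wald tests.

    Conditions are dicts with keys among {env, sp, size}; ``at_size`` is the
    common evaluation size unless a condition overrides it. Adjusted across
    all coordinates with Benjamini-Hochberg (or "none").
    """
    warnings: list[str] = []
    if size_range is not None and not (
        size_range[0] <= at_size <= size_range[1]
    ):
        warnings.append(
            f"evaluation size {at_size} outside observed range {size_range}"
        )

    ests, ps = [], []
    for c in models.coord_columns:
        fit = models.fits[c]

        def row(cond_spec: dict) -> np.ndarray:
            env = cond_spec.get("env", fit.env_levels[0])
            sp = cond_spec.get("sp", fit.sp_levels[0])
            size = cond_spec.get("size", at_size)
            return fit.design(
                np.array([env], dtype=object),
                np.array([size], dtype=float),
                np.array([sp], dtype=object),
            )[0]

        est, _, p = fit.contrast(row(condition_a), row(condition_b))
        ests.append(est)
        ps.append(p)

    ps_arr = np.asarray(ps)
    adj = _bh_adjust(ps_arr) if adjust == "bh" else ps_arr.copy()
    n_lm = len(models.coord_columns) // 2
    rows = []
    for i in range(n_lm):
        ix, iy = 2 * i, 2 * i + 1
        rows.append(
            {
                "landmark": i + 1,
                "dx": ests[ix],
                "dy": ests[iy],
                "p_x": ps_arr[ix],
                "p_y": ps_arr[iy],
                "p_adj_x": adj[ix],
                "p_adj_y": adj[iy],
                "significant": bool(adj[ix] < alpha or adj[iy] < alpha),
            }
        )
    return DeformationField(
        landmarks=pd.DataFrame(rows),
        condition_a=condition_a,
        condition_b=condition_b,
        at_size=at_size,
        warnings=warnings,
    )


@dataclass
class HybridShapeTest:
    deviations: pd.DataFrame       # id, coordinate, observed, expected, D
    displacement: pd.DataFrame     # landmark, mean dx, dy of observed-expected
    deviation_models: dict[str, cond.DeviationModelFit]


def hybrid_shape_test(
    models: ShapeModelSet,
    hybrid_aligned: pd.DataFrame,
    hybrid_covariates: pd.DataFrame,
    fit_models: bool = True,
) -> HybridShapeTest:
    """Test hybrid shapes against the h-mixture of pure-species predictions.

    Per coordinate, the expectation is h*pred(Pt) + (1-h)*pred(Cn) at the
    hybrid's size and environment; deviations D are modelled with the same
    env x size x h deviation model used for condition.
    """
    df = hybrid_aligned.merge(hybrid_covariates, on="id", how="inner")
    if df.empty:
        raise cond.FitError("no overlap between hybrid shapes and covariates")
    long_rows = []
    dev_by_coord: dict[str, pd.DataFrame] = {}
    for c in models.coord_columns:
        fit = models.fits[c]
        expected = cond.predict_hybrid_mixture(fit, df)
        observed = df[c].to_numpy(dtype=float)
        dev = pd.DataFrame(
            {
                "id": df["id"],
                "env": df["env"],
                "size_cm": df["size_cm"],
                "h": df["h"],
                "observed": observed,
                "expected": expected,
                "D": observed - expected,
            }
        )
        dev_by_coord[c] = dev
        long_rows.append(dev.assign(coordinate=c))
    deviations = pd.concat(long_rows, ignore_index=True)

    n_lm = len(models.coord_columns) // 2
    disp_rows = []
    for i in range(n_lm):
        cx, cy = models.coord_columns[2 * i], models.coord_columns[2 * i + 1]
        disp_rows.append(
            {
                "landmark": i + 1,
                "dx": float(dev_by_coord[cx]["D"].mean()),
                "dy": float(dev_by_coord[cy]["D"].mean()),
            }
        )

    dev_models: dict[str, cond.DeviationModelFit] = {}
    if fit_models and len(df) >= 8:
        for c in models.coord_columns:
            try:
                dev_models[c] = cond.fit_deviation_model(dev_by_coord[c])
            except cond.FitError:
                continue
    return HybridShapeTest(
        deviations=deviations,
        displacement=pd.DataFrame(disp_rows),
        deviation_models=dev_models,
    )


def plot_deformation(field: DeformationField, consensus: np.ndarray,
                     path: str, arrow_scale: float = 1.0) -> None:
    """Arrow plot of a deformation field over the consensus (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(consensus[:, 0], consensus[:, 1], "o", color="0.6", ms=4)
    for _, r in field.landmarks.iterrows():
        i = int(r["landmark"]) - 1
        color = "tab:red" if r["significant"] else "0.7"
        ax.annotate(
            "",
            xy=(consensus[i, 0] + arrow_scale * r["dx"],
                consensus[i, 1] + arrow_scale * r["dy"]),
            xytext=(consensus[i, 0], consensus[i, 1]),
            arrowprops={"arrowstyle": "->", "color": color},
        )
    ax.set_aspect("equal")
    ax.set_title(f"{field.condition_a} -> {field.condition_b}")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
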