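"""Condition coefficient and species x environment x size trait models.

The condition coefficient is ``K = weight (mg) / size (cm)^3``; records with
K < 5 or K > 20 are flagged as excluded (strict inequalities). Traits are
modelled with the full-interaction linear model

    trait = env x basis(size - median, m) x sp + error

where the basis is an orthogonalised polynomial of degree m (a B-spline
basis is available as an option), m in {1..5} is selected by Gaussian AIC,
and effects are tested with type-III partial F-tests under sum-to-zero
contrasts. Hybrid phenotypes are compared against the linear mixture
``h * pred(Pt) + (1 - h) * pred(Cn)`` and the per-individual deviation D is
itself modelled as ``D = env x size x h + error``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from hybeco.genetics import CN, PT

K_LOW = 5.0
K_HIGH = 20.0


class FitError(ValueError):
    """Raised for rank-deficient or otherwise unusable designs."""


@dataclass(frozen=True)
class ConditionRecord:
    individual: str
    k: float
    excluded: bool


def compute_k(size_cm: float, weight_mg: float,
              individual: str = "") -> ConditionRecord:
    """Condition coefficient K = weight/size^3 with the exclusion flag."""
    if size_cm <= 0 or weight_mg <= 0:
        raise ValueError(
            f"size and weight must be positive, got size={size_cm}, "
            f"weight={weight_mg}"
        )
    k = weight_mg / size_cm**3
    return ConditionRecord(individual, k, excluded=(k < K_LOW or k > K_HIGH))


def compute_k_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised K over a covariate table with size_cm/weight_mg columns."""
    if (df["size_cm"] <= 0).any() or (df["weight_mg"] <= 0).any():
        bad = df.loc[(df["size_cm"] <= 0) | (df["weight_mg"] <= 0), "id"]
        raise ValueError(f"non-positive size/weight for ids: {list(bad)}")
    out = df.copy()
    out["K"] = out["weight_mg"] / out["size_cm"] ** 3
    out["excluded"] = (out["K"] < K_LOW) | (out["K"] > K_HIGH)
    return out


# ---------------------------------------------------------------------------
# basis constructions
# ---------------------------------------------------------------------------

class PolyBasis:
    """Orthogonalised polynomial basis of a given degree.

    Columns reproduce the QR-orthonormalised Vandermonde of the training
    points; the stored triangular factor maps new points onto the same basis
    (the construction used by R's ``poly``).
    """

    kind = "poly"

    def __init__(self, x: np.ndarray, degree: int) -> None:
        if degree < 1:
            raise ValueError("degree must be >= 1")
        self.degree = degree
        x = np.asarray(x, dtype=float)
        V = np.vander(x, degree + 1, increasing=True)
        _, R = np.linalg.qr(V)
        signs = np.sign(np.diag(R))
        signs[signs == 0] = 1.0
        # unit-RMS columns: basis values are invariant to row replication
        self._Rinv = np.linalg.inv(R * signs[:, None] / np.sqrt(len(x)))

    def transform(self, x: np.ndarray) -> np.ndarray:
        V = np.vander(np.asarray(x, dtype=float), self.degree + 1,
                      increasing=True)
        return (V @ self._Rinv)[:, 1:]  # constant column dropped

    @property
    def n_cols(self) -> int:
        return self.degree


class SplineBasis:
    """Cubic B-spline basis with ``degree`` degrees of freedom."""

    kind = "bspline"

    def __init__(self, x: np.ndarray, degree: int) -> None:
        from patsy import dmatrix

        self.degree = max(degree, 3)  # bs needs df >= order - 1
        dm = dmatrix(
            f"bs(x, df={self.degree}, include_intercept=False) - 1",
            {"x": np.asarray(x, dtype=float)},
        )
        self._design_info = dm.design_info

    def transform(self, x: np.ndarray) -> np.ndarray:
        from patsy import build_design_matrices

        (dm,) = build_design_matrices(
            [self._design_info], {"x": np.asarray(x, dtype=float)}
        )
        return np.asarray(dm)

    @property
    def n_cols(self) -> int:
        return self.degree


def sum_contrasts(levels: Sequence[str]) -> dict[str, np.ndarray]:
    """Sum-to-zero contrast rows per level (k levels -> k-1 columns)."""
    k = len(levels)
    rows: dict[str, np.ndarray] = {}
    for i, lev in enumerate(levels):
        if i < k - 1:
            row = np.zeros(k - 1)
            row[i] = 1.0
        else:
            row = -np.ones(k - 1)
        rows[lev] = row
    return rows


# ---------------------------------------------------------------------------
# trait model
# ---------------------------------------------------------------------------

@dataclass
class TraitModelFit:
    """Fitted env x basis(size) x sp model for one response."""

    response: str
    degree: int
    basis: PolyBasis | SplineBasis
    size_center: float
    env_levels: list[str]
    sp_levels: list[str]
    coef: pd.Series = field(repr=False)
    cov: np.ndarray = field(repr=False)
    sigma2: float = 0.0
    df_resid: int = 0
    aic_table: dict[int, float] = field(default_factory=dict)
    type3: pd.DataFrame | None = None
    term_slices: dict[str, list[int]] = field(default_factory=dict)
    n_obs: int = 0

    # -- design ------------------------------------------------------------
    def design(self, env: np.ndarray, size: np.ndarray,
               sp: np.ndarray) -> np.ndarray:
        env = np.asarray(env, dtype=object)
        sp = np.asarray(sp, dtype=object)
        size = np.asarray(size, dtype=float)
        n = len(size)
        env_c = sum_contrasts(self.env_levels)
        sp_c = sum_contrasts(self.sp_levels)
        for lev in np.unique(env):
            if lev not in env_c:
                raise ValueError(f"unseen environment level {lev!r}")
        for lev in np.unique(sp):
            if lev not in sp_c:
                raise ValueError(f"unseen species level {lev!r}")
        E = np.vstack([env_c[e] for e in env]) if len(self.env_levels) > 1 \
            else np.empty((n, 0))
        S = np.vstack([sp_c[s] for s in sp]) if len(self.sp_levels) > 1 \
            else np.empty((n, 0))
        B = self.basis.transform(size - self.size_center)
        blocks = {
            "Intercept": np.ones((n, 1)),
            "env": E,
            "size": B,
            "sp": S,
            "env:size": _rowwise_kron(E, B),
            "env:sp": _rowwise_kron(E, S),
            "size:sp": _rowwise_kron(B, S),
            "env:size:sp": _rowwise_kron(_rowwise_kron(E, B), S),
        }
        cols = [blocks[t] for t in self.term_order() if blocks[t].shape[1]]
        return np.hstack(cols)

    def term_order(self) -> list[str]:
        return ["Intercept", "env", "size", "sp",
                "env:size", "env:sp", "size:sp", "env:size:sp"]

    # -- prediction ----------------------------------------------------------
    def predict(self, env, size, sp) -> np.ndarray:
        env, size, sp = np.atleast_1d(env), np.atleast_1d(size), np.atleast_1d(sp)
        n = max(len(env), len(size), len(sp))
        env = np.resize(env, n)
        size = np.resize(size, n)
        sp = np.resize(sp, n)
        X = self.design(env, size, sp)
        return X @ self.coef.values

    def contrast(self, row_a: np.ndarray, row_b: np.ndarray
                 ) -> tuple[float, float, float]:
        """Wald test of pred(b) - pred(a): (estimate, se, p)."""
        c = row_b - row_a
        est = float(c @ self.coef.values)
        se = float(np.sqrt(c @ self.cov @ c))
        if se == 0.0:
            return est, 0.0, 1.0 if est == 0.0 else 0.0
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), self.df_resid)
        return est, se, p


def _rowwise_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if a.shape[1] == 0 or b.shape[1] == 0:
        return np.empty((a.shape[0], 0))
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def _term_labels(fit: TraitModelFit) -> list[str]:
    env_l = fit.env_levels[:-1]
    sp_l = fit.sp_levels[:-1]
    size_l = [f"size^{i + 1}" if fit.basis.kind == "poly" else f"bs{i + 1}"
              for i in range(fit.basis.n_cols)]
    labels = ["Intercept"]
    parts = {
        "env": [f"env[{e}]" for e in env_l],
        "size": size_l,
        "sp": [f"sp[{s}]" for s in sp_l],
    }
    for term in fit.term_order()[1:]:
        factors = term.split(":")
        combos = itertools.product(*(parts[f] for f in factors))
        labels.extend(":".join(c) for c in combos)
    return labels


def _fit_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares; returns (beta, rss, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), rank


def _gaussian_aic(rss: float, n: int, k_params: int) -> float:
    # profile Gaussian log-likelihood; +1 for the variance parameter
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * (k_params + 1)


def fit_trait_model(
    data: pd.DataFrame,
    response: str,
    candidate_degrees: Sequence[int] = (1, 2, 3, 4, 5),
    size_col: str = "size_cm",
    env_col: str = "env",
    sp_col: str = "sp",
    size_center: float | None = None,
    basis: str = "poly",
    compute_type3: bool = True,
) -> TraitModelFit:
    """Fit the env x basis(size, m) x sp model, selecting m by AIC.

    ``data`` holds non-excluded records only. The size variable is centred
    on the dataset median unless ``size_center`` is given. Type-III tests
    are partial F-tests: each term against the model holding all others.
    """
    if any(d >= 6 or d < 1 for d in candidate_degrees):
        raise ValueError("candidate degrees must lie in 1..5")
    df = data.dropna(subset=[response, size_col, env_col, sp_col])
    y = df[response].to_numpy(dtype=float)
    n = len(df)
    if n < 10:
        raise FitError(f"too few records ({n}) to fit {response}")
    env_levels = sorted(df[env_col].astype(str).unique())
    sp_levels = sorted(df[sp_col].astype(str).unique())
    cells = df.groupby([env_col, sp_col]).size()
    for e in env_levels:
        for s in sp_levels:
            if (e, s) not in cells.index:
                raise FitError(
                    f"empty design cell env={e!r} x sp={s!r} for {response}"
                )
    center = float(df[size_col].median()) if size_center is None else size_center

    basis_cls = PolyBasis if basis == "poly" else SplineBasis
    sizes = df[size_col].to_numpy(dtype=float)
    env = df[env_col].astype(str).to_numpy()
    sp = df[sp_col].astype(str).to_numpy()

    fits: dict[int, tuple[TraitModelFit, np.ndarray, float]] = {}
    aic_table: dict[int, float] = {}
    for m in candidate_degrees:
        b = basis_cls(sizes - center, m)
        fit = TraitModelFit(
            response=response, degree=m, basis=b, size_center=center,
            env_levels=env_levels, sp_levels=sp_levels,
            coef=pd.Series(dtype=float), cov=np.empty((0, 0)),
        )
        X = fit.design(env, sizes, sp)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # not enough support for this degree; lower degrees may still fit
            continue
        beta, rss, _ = _fit_ols(X, y)
        aic_table[m] = _gaussian_aic(rss, n, X.shape[1])
        fits[m] = (fit, X, rss)
        fit.coef = pd.Series(beta, index=_term_labels(fit))

    if not fits:
        raise FitError(
            f"rank-deficient design for {response} at all candidate degrees"
        )
    best = min(aic_table, key=lambda m: (aic_table[m], m))
    fit, X, rss = fits[best]
    df_resid = n - X.shape[1]
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    fit.cov = sigma2 * xtx_inv
    fit.sigma2 = sigma2
    fit.df_resid = df_resid
    fit.aic_table = dict(aic_table)
    fit.n_obs = n

    # map coefficient indices to terms for type-III drops
    sizes_by_term = {
        "Intercept": 1,
        "env": len(env_levels) - 1,
        "size": fit.basis.n_cols,
        "sp": len(sp_levels) - 1,
    }
    sizes_by_term["env:size"] = sizes_by_term["env"] * sizes_by_term["size"]
    sizes_by_term["env:sp"] = sizes_by_term["env"] * sizes_by_term["sp"]
    sizes_by_term["size:sp"] = sizes_by_term["size"] * sizes_by_term["sp"]
    sizes_by_term["env:size:sp"] = (
        sizes_by_term["env"] * sizes_by_term["size"] * sizes_by_term["sp"]
    )
    pos = 0
    term_slices: dict[str, list[int]] = {}
    for term in fit.term_order():
        width = sizes_by_term[term]
        term_slices[term] = list(range(pos, pos + width))
        pos += width
    fit.term_slices = term_slices

    if compute_type3:
        rows = []
        for term in fit.term_order()[1:]:
            idx = term_slices[term]
            if not idx:
                continue
            keep = [j for j in range(X.shape[1]) if j not in idx]
            _, rss_r, _ = _fit_ols(X[:, keep], y)
            df_num = len(idx)
            f = ((rss_r - rss) / df_num) / (rss / df_resid)
            p = stats.f.sf(f, df_num, df_resid)
            rows.append({"effect": term, "df": df_num, "F": f, "p": p})
        fit.type3 = pd.DataFrame(rows)
    return fit


def predict_hybrid_mixture(
    fit: TraitModelFit, hybrids: pd.DataFrame,
    size_col: str = "size_cm", env_col: str = "env", h_col: str = "h",
) -> np.ndarray:
    """Mixture prediction h*pred(Pt) + (1-h)*pred(Cn) per hybrid row."""
    env = hybrids[env_col].astype(str).to_numpy()
    size = hybrids[size_col].to_numpy(dtype=float)
    h = hybrids[h_col].to_numpy(dtype=float)
    pred_pt = fit.predict(env, size, np.full(len(env), PT, dtype=object))
    pred_cn = fit.predict(env, size, np.full(len(env), CN, dtype=object))
    return h * pred_pt + (1.0 - h) * pred_cn


def hybrid_deviations(
    fit: TraitModelFit, hybrids: pd.DataFrame, observed_col: str,
    size_col: str = "size_cm", env_col: str = "env", h_col: str = "h",
) -> pd.DataFrame:
    """Observed minus mixture-predicted trait per hybrid (column D)."""
    pred = predict_hybrid_mixture(fit, hybrids, size_col, env_col, h_col)
    out = hybrids.copy()
    out["predicted"] = pred
    out["D"] = out[observed_col].to_numpy(dtype=float) - pred
    return out


@dataclass
class DeviationModelFit:
    params: pd.DataFrame         # coef, se, t, p per term
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    notes: list[str]
    result: object = field(repr=False, default=None)


def fit_deviation_model(
    deviations: pd.DataFrame,
    env_col: str = "env", size_col: str = "size_cm", h_col: str = "h",
    d_col: str = "D",
) -> DeviationModelFit:
    """OLS of D on the full env x size x h interaction design.

    A single environment level drops the env terms with an explicit note
    (never silently absorbed).
    """
    df = deviations.rename(
        columns={env_col: "env", size_col: "size", h_col: "h", d_col: "D"}
    )[["env", "size", "h", "D"]].dropna()
    if len(df) < 2:
        raise FitError("need at least 2 hybrids to fit the deviation model")
    notes: list[str] = []
    env_levels = df["env"].astype(str).unique()
    if len(env_levels) > 1:
        formula = "D ~ C(env, Sum) * size * h"
    else:
        formula = "D ~ size * h"
        notes.append(
            f"single environment level {env_levels[0]!r}: env terms dropped"
        )
    res = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise FitError("collinear deviation-model design")
    params = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    fval = float(res.fvalue) if res.df_model > 0 else np.nan
    fp = float(res.f_pvalue) if res.df_model > 0 else np.nan
    return DeviationModelFit(
        params=params,
        f_statistic=fval,
        f_pvalue=fp,
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        notes=notes,
        result=res,
    )


def size_age_comparison(
    records: pd.DataFrame,
    group_col: str = "group", env_col: str = "env",
    size_col: str = "size_cm", age_col: str = "age",
    exclude_stations: Sequence[str] = (),
    station_col: str = "station",
) -> dict:
    """Age-adjusted group x env mean-size comparison (ANCOVA, type III).

    Fits ``size ~ group x env + age``; reports adjusted means at the overall
    mean age, pairwise group differences, and type-III tests. Records with
    missing age are excluded and counted.
    """
    df = records.copy()
    if exclude_stations and station_col in df.columns:
        df = df[~df[station_col].isin(set(exclude_stations))]
    n_missing_age = int(df[age_col].isna().sum())
    df = df.dropna(subset=[age_col, size_col, group_col, env_col])
    df = df.rename(columns={group_col: "group", env_col: "env",
                            size_col: "size", age_col: "age"})
    model = smf.ols("size ~ C(group, Sum) * C(env, Sum) + age", data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise FitError(
            "rank-deficient size~group*env+age design (confounded covariates)"
        )
    res = model.fit()
    type3 = sm.stats.anova_lm(res, typ=3)

    mean_age = float(df["age"].mean())
    combos = df.groupby(["group", "env"]).size().reset_index()[["group", "env"]]
    pred_df = combos.assign(age=mean_age)
    pr = res.get_prediction(pred_df).summary_frame(alpha=0.05)
    adjusted = combos.assign(
        adjusted_mean=pr["mean"].to_numpy(), se=pr["mean_se"].to_numpy()
    )
    return {
        "fit": res,
        "type3": type3,
        "adjusted_means": adjusted,
        "n_missing_age": n_missing_age,
        "n_used": len(df),
    }
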