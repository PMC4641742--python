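"""Feeding activity, feeding index and diet classification.

Feeding activity models feces presence (gut vacuity indicator) with the
logistic design ``logit P(present) = h x (season + size + env)``, i.e. main
effects of h, season, size and env plus the h:season, h:size and h:env
interactions. The feeding index is the first principal axis of a centred
PCA on row-normalised prey compositions, oriented so that it correlates
positively with the diatom proportion. Diet classes follow the deterministic
detection-pattern rule (only invertebrates / both / only diatoms / nothing)
and feed a 3-category baseline-logit multinomial model (omnivore baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from patsy import dmatrices

from hybeco.simulate import DEFAULT_PREY_ITEMS, DEFAULT_PREY_GROUPS

INVERTEBRATE_EATER = "invertebrate_eater"
OMNIVORE = "omnivore"
DIATOM_EATER = "diatom_eater"
NO_DETECTION = "no_detection"

DEFAULT_ITEM_GROUPS: dict[str, str] = dict(
    zip(DEFAULT_PREY_ITEMS, DEFAULT_PREY_GROUPS)
)


class DietEstimationError(ValueError):
    pass


def classify_diet(
    detections: Mapping[str, int],
    item_groups: Mapping[str, str] | None = None,
) -> str:
    """Deterministic diet class from one binary detection pattern."""
    groups = DEFAULT_ITEM_GROUPS if item_groups is None else item_groups
    has_diatom = any(
        int(v) == 1 for k, v in detections.items()
        if groups[k] == "diatom"
    )
    has_invert = any(
        int(v) == 1 for k, v in detections.items()
        if groups[k] == "invertebrate"
    )
    if has_diatom and has_invert:
        return OMNIVORE
    if has_diatom:
        return DIATOM_EATER
    if has_invert:
        return INVERTEBRATE_EATER
    return NO_DETECTION


def classify_diet_table(
    prey: pd.DataFrame,
    item_groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Classify every row of a prey matrix (id column + item columns)."""
    groups = DEFAULT_ITEM_GROUPS if item_groups is None else item_groups
    items = [c for c in prey.columns if c in groups]
    labels = [
        classify_diet(row[items].to_dict(), groups)
        for _, row in prey.iterrows()
    ]
    return pd.DataFrame({"id": prey["id"], "diet_class": labels})


@dataclass
class FeedingIndex:
    scores: pd.Series                 # per analysed individual
    explained_inertia: float
    loadings: pd.Series
    excluded_ids: list[str]
    compositions: pd.DataFrame = field(repr=False, default=None)


def feeding_index_pca(
    prey: pd.DataFrame,
    item_groups: Mapping[str, str] | None = None,
    mode: str = "proportion",
) -> FeedingIndex:
    """First-axis score of the composition PCA (the feeding index).

    Rows are normalised to proportions (detections / total detections);
    zero-detection rows are excluded and reported. The axis sign is fixed so
    that the correlation between scores and diatom proportion is >= 0.
    ``mode="presence"`` skips the normalisation (raw 0/1 PCA alternative).
    """
    groups = DEFAULT_ITEM_GROUPS if item_groups is None else item_groups
    items = [c for c in prey.columns if c in groups]
    if not items:
        raise DietEstimationError("no prey item columns found")
    X = prey[items].to_numpy(dtype=float)
    totals = X.sum(axis=1)
    keep = totals > 0
    excluded = list(prey.loc[~keep, "id"])
    if keep.sum() < 2:
        raise DietEstimationError(
            "need >= 2 individuals with at least one detection"
        )
    ids = prey.loc[keep, "id"].to_numpy()
    comp = X[keep] / totals[keep, None] if mode == "proportion" else X[keep]
    centred = comp - comp.mean(axis=0)
    _, s, Vt = np.linalg.svd(centred, full_matrices=False)
    scores = centred @ Vt[0]
    inertia = float(s[0] ** 2 / (s**2).sum())

    diatom_items = [i for i, it in enumerate(items) if groups[it] == "diatom"]
    diatom_prop = comp[:, diatom_items].sum(axis=1)
    if np.std(diatom_prop) > 0 and np.std(scores) > 0:
        r = np.corrcoef(scores, diatom_prop)[0, 1]
        if r < 0:
            scores = -scores
            Vt = Vt.copy()
            Vt[0] = -Vt[0]
    return FeedingIndex(
        scores=pd.Series(scores, index=ids, name="feeding_index"),
        explained_inertia=inertia,
        loadings=pd.Series(Vt[0], index=items),
        excluded_ids=excluded,
        compositions=pd.DataFrame(comp, index=ids, columns=items),
    )


# ---------------------------------------------------------------------------
# vacuity (feeding activity) logistic model
# ---------------------------------------------------------------------------

@dataclass
class VacuityFit:
    params: pd.DataFrame          # coef, se, z, p
    lr_tests: pd.DataFrame        # term, lr_chi2, df, p
    notes: list[str]
    result: object = field(repr=False, default=None)


def fit_vacuity_model(
    records: pd.DataFrame,
    response: str = "feces",
    h_col: str = "h",
    season_col: str = "season",
    size_col: str = "size_cm",
    env_col: str = "env",
) -> VacuityFit:
    """Logistic model logit P(feces) = h x (season + size + env).

    Degenerate single-level factors are dropped with a logged note.
    Likelihood-ratio tests are reported per term (each term dropped from the
    full model).
    """
    df = records.rename(
        columns={response: "y", h_col: "h", season_col: "season",
                 size_col: "size", env_col: "env"}
    )[["y", "h", "season", "size", "env"]].dropna()
    if df["y"].nunique() < 2:
        raise DietEstimationError("response has a single value")
    notes: list[str] = []
    terms = ["h", "size", "h:size"]
    for fac in ("season", "env"):
        if df[fac].nunique() > 1:
            terms.insert(-1, f"C({fac})")
            terms.append(f"h:C({fac})")
        else:
            notes.append(f"single-level factor {fac!r}: terms dropped")
    formula = "y ~ " + " + ".join(terms)

    def fit_formula(f: str):
        y, X = dmatrices(f, df, return_type="dataframe")
        return sm.Logit(y, X).fit(disp=0, maxiter=200), X

    try:
        res, X = fit_formula(formula)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise DietEstimationError(
            f"logistic estimation failed (possible separation): {exc}"
        ) from exc
    if not np.isfinite(res.params).all() or (np.abs(res.params) > 50).any():
        big = res.params[np.abs(res.params) > 50].index.tolist()
        raise DietEstimationError(
            f"complete or quasi-complete separation on terms: {big}"
        )

    lr_rows = []
    for term in terms:
        reduced_terms = [t for t in terms if t != term]
        # hierarchy: dropping a main effect also drops its interactions
        reduced_terms = [
            t for t in reduced_terms
            if not (":" in t and term in t.split(":"))
        ]
        f_red = "y ~ " + (" + ".join(reduced_terms) if reduced_terms else "1")
        res_red, _ = fit_formula(f_red)
        lr = 2.0 * (res.llf - res_red.llf)
        dfree = res.df_model - res_red.df_model
        lr_rows.append(
            {
                "term": term.replace("C(", "").replace(")", ""),
                "lr_chi2": max(lr, 0.0),
                "df": int(dfree),
                "p": stats.chi2.sf(max(lr, 0.0), dfree) if dfree > 0 else np.nan,
            }
        )
    params = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
    )
    return VacuityFit(
        params=params, lr_tests=pd.DataFrame(lr_rows), notes=notes, result=res
    )


# ---------------------------------------------------------------------------
# multinomial diet model
# ---------------------------------------------------------------------------

CLASS_ORDER = [OMNIVORE, INVERTEBRATE_EATER, DIATOM_EATER]


@dataclass
class MultinomialDietFit:
    params: pd.DataFrame          # coefficients per non-baseline class
    lr_tests: pd.DataFrame        # term, lr_chi2, df, p
    classes: list[str]
    notes: list[str]
    result: object = field(repr=False, default=None)
    design_info: object = field(repr=False, default=None)

    def predict_proba(self, newdata: pd.DataFrame) -> pd.DataFrame:
        from patsy import build_design_matrices

        (X,) = build_design_matrices([self.design_info], newdata)
        probs = self.result.predict(np.asarray(X))
        return pd.DataFrame(probs, columns=self.classes)


def fit_diet_multinomial(
    data: pd.DataFrame,
    class_col: str = "diet_class",
    terms: Sequence[str] = ("C(season)", "C(env)", "C(group)", "size"),
    rename: Mapping[str, str] | None = None,
) -> MultinomialDietFit:
    """Baseline-logit multinomial model of the 3 diet classes.

    Omnivore is the baseline category. ``no_detection`` rows must already be
    excluded. Per-term likelihood-ratio chi-square tests are computed by
    refitting without the term.
    """
    df = data.copy()
    if rename:
        df = df.rename(columns=rename)
    df = df[df[class_col] != NO_DETECTION].dropna(
        subset=[class_col]
    )
    present = [c for c in CLASS_ORDER if c in set(df[class_col])]
    if len(present) < 2:
        raise DietEstimationError(
            f"need >= 2 diet classes, found {present}"
        )
    notes: list[str] = []
    kept_terms: list[str] = []
    for t in terms:
        if t.startswith("C(") and df[t[2:-1]].nunique() < 2:
            notes.append(f"single-level factor {t!r}: dropped")
        else:
            kept_terms.append(t)
    # class codes: baseline (omnivore) must be 0 for MNLogit
    code_of = {lab: i for i, lab in enumerate(present)}
    df["_cls"] = df[class_col].map(code_of)

    formula = "_cls ~ " + (" + ".join(kept_terms) if kept_terms else "1")
    y, X = dmatrices(formula, df, return_type="dataframe")
    y = df.loc[X.index, "_cls"]

    def fit_X(Xm: pd.DataFrame):
        import warnings

        model = sm.MNLogit(y.loc[Xm.index], Xm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                res = model.fit(disp=0, method="bfgs", maxiter=2000,
                                start_params=res.params)
        return res

    try:
        res = fit_X(X)
    except Exception as exc:
        raise DietEstimationError(f"multinomial estimation failed: {exc}") from exc
    if not np.isfinite(res.params.to_numpy()).all() or (
        np.abs(res.params.to_numpy()) > 50
    ).any():
        raise DietEstimationError("quasi-separation in multinomial fit")

    lr_rows = []
    di = X.design_info
    for t in kept_terms:
        cols = di.term_name_slices[t]
        keep_cols = [
            c for i, c in enumerate(X.columns)
            if not (cols.start <= i < cols.stop)
        ]
        res_red = fit_X(X[keep_cols])
        lr = 2.0 * (res.llf - res_red.llf)
        dfree = (X.shape[1] - len(keep_cols)) * (len(present) - 1)
        lr_rows.append(
            {
                "term": t.replace("C(", "").replace(")", ""),
                "lr_chi2": max(lr, 0.0),
                "df": int(dfree),
                "p": stats.chi2.sf(max(lr, 0.0), dfree),
            }
        )

    param_frames = []
    for j, lab in enumerate(present[1:]):
        block = pd.DataFrame(
            {
                "class": lab,
                "term": X.columns,
                "coef": res.params.iloc[:, j].to_numpy(),
                "se": res.bse.iloc[:, j].to_numpy(),
            }
        )
        param_frames.append(block)
    params = pd.concat(param_frames, ignore_index=True)
    params["z"] = params["coef"] / params["se"]
    params["p"] = 2.0 * stats.norm.sf(np.abs(params["z"]))
    return MultinomialDietFit(
        params=params,
        lr_tests=pd.DataFrame(lr_rows),
        classes=present,
        notes=notes,
        result=res,
        design_info=di,
    )


def class_proportions(
    data: pd.DataFrame,
    class_col: str = "diet_class",
    by: Sequence[str] = ("group", "zone"),
) -> pd.DataFrame:
    """Stacked class-proportion summary (modelled classes only)."""
    df = data[data[class_col] != NO_DETECTION]
    counts = (
        df.groupby([*by, class_col], observed=True).size().rename("n").reset_index()
    )
    totals = counts.groupby(list(by), observed=True)["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    return counts
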