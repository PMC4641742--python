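"""End-to-end orchestration: simulate -> genetics -> condition -> morpho -> diet.

A run is driven by a :class:`RunConfig` (YAML-loadable). Every stage logs
record counts in/out, all randomness flows from the single run seed, and all
outputs are delimited text files under the output directory, so a rerun with
the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

import hybeco
from hybeco import condition as cond
from hybeco import diet as diet_mod
from hybeco import genetics, morpho, simulate
from hybeco.genetics import CN, PT, HYBRID

logger = logging.getLogger("hybeco")

_FLOAT_FMT = "%.10g"


class IntegrityError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "hybeco_out"
    seed: int = 0
    simulation: dict[str, Any] | None = field(default_factory=dict)
    inputs: dict[str, str] | None = None   # genotypes, covariates, landmarks,
                                           # prey, mtdna (paths)
    cn_threshold: float = genetics.CN_UPPER
    pt_threshold: float = genetics.PT_LOWER
    alpha: float = 0.05
    adjust: str = "bh"
    evaluation_size: str | float = "median"
    basis: str = "poly"
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "genetics": True, "condition": True, "morpho": True, "diet": True,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.cn_threshold < self.pt_threshold < 1.0:
            raise ValueError(
                "class thresholds must satisfy 0 < t_low < t_high < 1"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def canonical(self) -> str:
        """Analytic configuration only: output location is excluded so two
        runs of the same analysis hash identically."""
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "out_dir"
        }
        return yaml.safe_dump(d, sort_keys=True)


def validate_inputs(
    covariates: pd.DataFrame,
    genotype_ids: list[str] | None = None,
    landmarks: dict[str, np.ndarray] | None = None,
    prey: pd.DataFrame | None = None,
    expected_landmarks: int = morpho.N_LANDMARKS,
) -> pd.DataFrame:
    """Cross-table sanity checks; returns a severity-tagged report table."""
    issues: list[dict[str, str]] = []

    dup = covariates["id"][covariates["id"].duplicated()]
    for d in dup:
        issues.append({"severity": "error", "message": f"duplicate id {d!r}"})

    if {"size_cm", "weight_mg"}.issubset(covariates.columns):
        sz = covariates["size_cm"]
        if ((sz < 1) | (sz > 120)).any():
            issues.append(
                {"severity": "warning",
                 "message": "size_cm outside plausible 1-120 cm range"}
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            k = covariates["weight_mg"] / sz**3
        med = float(np.nanmedian(k))
        if med < 1.0:
            issues.append(
                {"severity": "warning",
                 "message": f"median K={med:.4g} << 5: weight probably in "
                            "grams, expected mg"}
            )
        elif med > 100.0:
            issues.append(
                {"severity": "warning",
                 "message": f"median K={med:.4g} >> 20: check weight units"}
            )

    ids = set(covariates["id"])
    if genotype_ids is not None:
        orphans = sorted(set(genotype_ids) - ids)
        if orphans:
            issues.append(
                {"severity": "error",
                 "message": f"{len(orphans)} genotyped ids missing from "
                            f"covariates: {orphans[:10]}"}
            )
    if landmarks is not None:
        for spec_id, arr in landmarks.items():
            if np.asarray(arr).shape != (expected_landmarks, 2):
                issues.append(
                    {"severity": "error",
                     "message": f"{spec_id}: landmark array shape "
                                f"{np.asarray(arr).shape}, expected "
                                f"({expected_landmarks}, 2)"}
                )
    if prey is not None and len(prey):
        items = [c for c in prey.columns if c != "id"]
        vals = prey[items].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            issues.append(
                {"severity": "error", "message": "non-binary prey entries"}
            )
    return pd.DataFrame(issues, columns=["severity", "message"])


def _write(df: pd.DataFrame, out_dir: str, name: str) -> str:
    path = os.path.join(out_dir, name)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return name


def _load_inputs(cfg: RunConfig) -> simulate.SyntheticDataset | dict[str, Any]:
    paths = cfg.inputs
    geno = genetics.read_genepop(paths["genotypes"])
    covariates = pd.read_csv(paths["covariates"])
    landmarks, rejected = morpho.read_tps(paths["landmarks"])
    prey = pd.read_csv(paths["prey"])
    mtdna = (
        genetics.read_mtdna(paths["mtdna"]) if "mtdna" in paths
        else dict(zip(covariates["id"], covariates.get("mtdna", [])))
    )
    return {
        "genotypes": geno,
        "covariates": covariates,
        "landmarks": landmarks,
        "prey": prey,
        "mtdna": mtdna,
        "tps_rejected": rejected,
    }


def _reference_panels(covariates: pd.DataFrame) -> dict[str, list[str]]:
    """Reference panel ids per species: pure species in the reference zone,
    falling back to pure species anywhere."""
    panels: dict[str, list[str]] = {}
    for sp in (CN, PT):
        mask = covariates["species"] == sp
        if "zone" in covariates.columns and (
            mask & (covariates["zone"] == "reference")
        ).any():
            mask = mask & (covariates["zone"] == "reference")
        panels[sp] = list(covariates.loc[mask, "id"])
        if not panels[sp]:
            raise IntegrityError(f"no reference individuals for {sp}")
    return panels


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all enabled stages; returns the run report (also written)."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {
            "package_version": hybeco.__version__,
            "seed": cfg.seed,
            "config_sha256": hashlib.sha256(
                cfg.canonical().encode()
            ).hexdigest(),
        },
        "stages": {},
        "tables": [],
    }

    # ----- data ------------------------------------------------------------
    if cfg.simulation is not None:
        sim_cfg = simulate.SimulationConfig.from_dict(
            {**(cfg.simulation or {}), "seed": cfg.seed}
        )
        dataset = simulate.gen_individuals(sim_cfg)
        data_dir = os.path.join(cfg.out_dir, "data")
        dataset.write(data_dir)
        covariates = dataset.covariates
        geno = dataset.genotypes
        landmarks = dataset.landmarks
        prey = dataset.prey
        mtdna = dict(zip(covariates["id"], covariates["mtdna"]))
        logger.info("simulate: %d individuals generated", len(covariates))
        report["stages"]["simulate"] = {"n_individuals": len(covariates)}
    else:
        if not cfg.inputs:
            raise StageError("no inputs and simulation disabled")
        loaded = _load_inputs(cfg)
        covariates = loaded["covariates"]
        geno = loaded["genotypes"]
        landmarks = loaded["landmarks"]
        prey = loaded["prey"]
        mtdna = loaded["mtdna"]

    validation = validate_inputs(
        covariates, geno.individuals, landmarks, prey
    )
    report["tables"].append(_write(validation, cfg.out_dir, "validation.csv"))
    errors = validation[validation["severity"] == "error"]
    if len(errors):
        raise IntegrityError("; ".join(errors["message"]))
    missing = sorted(set(geno.individuals) - set(covariates["id"]))
    if missing:
        raise IntegrityError(f"ids without covariates: {missing}")

    analysis = covariates.copy()
    analysis["env"] = analysis["zone"]

    # ----- genetics --------------------------------------------------------
    if cfg.stages.get("genetics", True):
        panels = _reference_panels(covariates)
        relabelled = genetics.GenotypeTable(
            individuals=list(geno.individuals),
            loci=list(geno.loci),
            genotypes=list(geno.genotypes),
            populations=[
                "refCn" if i in set(panels[CN])
                else ("refPt" if i in set(panels[PT]) else p)
                for i, p in zip(geno.individuals, geno.populations)
            ],
        )
        freqs = genetics.estimate_allele_frequencies(
            relabelled, {CN: ["refCn"], PT: ["refPt"]}
        )
        estimates = genetics.estimate_hybrid_indices(relabelled, freqs)
        estimates["mtdna"] = estimates["id"].map(mtdna)
        cls = [
            genetics.classify_genomic(
                h, m, cfg.cn_threshold, cfg.pt_threshold
            )
            for h, m in zip(estimates["h"], estimates["mtdna"])
        ]
        estimates["genomic_class"] = [c.label for c in cls]
        estimates["class_reason"] = [c.reason for c in cls]
        analysis = analysis.merge(
            estimates[["id", "h", "genomic_class"]], on="id", how="left"
        )
        station_summary = genetics.summarize_population(
            estimates["genomic_class"],
            estimates["h"],
            covariates.set_index("id").loc[estimates["id"], "station"],
        )
        report["tables"].append(
            _write(estimates.drop(columns=["population"]), cfg.out_dir,
                   "hybrid_index.csv")
        )
        report["tables"].append(
            _write(station_summary, cfg.out_dir, "station_summary.csv")
        )
        comp = estimates["genomic_class"].value_counts(normalize=True) * 100
        report["stages"]["genetics"] = {
            "n_estimated": len(estimates),
            "n_loci": len(freqs.loci),
            "dropped_loci": freqs.dropped_loci,
            "pct_by_class": {k: round(v, 3) for k, v in comp.items()},
        }
        logger.info("genetics: %d individuals, %d loci", len(estimates),
                    len(freqs.loci))
    else:
        analysis["h"] = np.nan
        analysis["genomic_class"] = analysis["species"]

    pure = analysis[analysis["genomic_class"].isin([CN, PT])].copy()
    hybrids = analysis[analysis["genomic_class"] == HYBRID].copy()

    # ----- condition -------------------------------------------------------
    if cfg.stages.get("condition", True):
        ktab = cond.compute_k_table(analysis)
        n_excluded = int(ktab["excluded"].sum())
        pure_k = ktab[
            ktab["genomic_class"].isin([CN, PT]) & ~ktab["excluded"]
        ].rename(columns={"genomic_class": "sp"})
        fit = cond.fit_trait_model(
            pure_k.assign(env=pure_k["zone"]), response="K",
            basis=cfg.basis,
        )
        hyb_k = ktab[
            (ktab["genomic_class"] == HYBRID) & ~ktab["excluded"]
        ].assign(env=lambda d: d["zone"])
        # the deviation model is restricted to environments actually holding
        # hybrids in numbers (the hybrid-zone basins)
        env_counts = hyb_k["env"].value_counts()
        hyb_k = hyb_k[hyb_k["env"].isin(env_counts[env_counts >= 5].index)]
        deviation_out: dict[str, Any] = {}
        if len(hyb_k) >= 8:
            devs = cond.hybrid_deviations(fit, hyb_k, observed_col="K")
            dev_fit = cond.fit_deviation_model(devs)
            report["tables"].append(
                _write(
                    devs[["id", "env", "size_cm", "h", "K", "predicted", "D"]],
                    cfg.out_dir, "condition_deviations.csv",
                )
            )
            report["tables"].append(
                _write(
                    dev_fit.params.reset_index(names="term"),
                    cfg.out_dir, "condition_deviation_model.csv",
                )
            )
            deviation_out = {
                "mean_D": round(float(devs["D"].mean()), 6),
                "global_F": round(dev_fit.f_statistic, 6),
                "global_F_p": round(dev_fit.f_pvalue, 6),
                "additivity_rejected": bool(dev_fit.f_pvalue < cfg.alpha),
                "notes": dev_fit.notes,
            }
        coef_table = fit.coef.reset_index()
        coef_table.columns = ["term", "coef"]
        report["tables"].append(
            _write(coef_table, cfg.out_dir, "condition_coefficients.csv")
        )
        report["tables"].append(
            _write(fit.type3, cfg.out_dir, "condition_type3.csv")
        )
        try:
            size_cmp = cond.size_age_comparison(
                analysis.rename(columns={"genomic_class": "group"})
            )
            report["tables"].append(
                _write(size_cmp["adjusted_means"], cfg.out_dir,
                       "size_adjusted_means.csv")
            )
        except cond.FitError as exc:  # e.g. empty group x env cells
            logger.warning("condition: size/age comparison skipped: %s", exc)
        report["stages"]["condition"] = {
            "n_records": len(ktab),
            "n_excluded_k": n_excluded,
            "selected_degree": fit.degree,
            "aic_table": {str(k): round(v, 4) for k, v in
                          fit.aic_table.items()},
            "hybrid_additivity": deviation_out,
        }
        logger.info("condition: %d records, %d K-outliers excluded",
                    len(ktab), n_excluded)

    # ----- morphometrics ---------------------------------------------------
    if cfg.stages.get("morpho", True):
        gpa = morpho.gpa_align(landmarks)
        coords = gpa.coordinate_table()
        report["tables"].append(
            _write(coords, cfg.out_dir, "aligned_coordinates.csv")
        )
        cons = pd.DataFrame(gpa.consensus, columns=["x", "y"])
        cons.insert(0, "landmark", np.arange(1, len(cons) + 1))
        report["tables"].append(_write(cons, cfg.out_dir, "consensus.csv"))

        pure_cov = pure.rename(columns={"genomic_class": "sp"})[
            ["id", "env", "sp", "size_cm"]
        ]
        models = morpho.fit_shape_models(coords, pure_cov, basis=cfg.basis)
        at_size = (
            float(pure_cov["size_cm"].median())
            if cfg.evaluation_size == "median"
            else float(cfg.evaluation_size)
        )
        dfield = morpho.deformation_between(
            models, {"sp": CN}, {"sp": PT}, at_size=at_size,
            alpha=cfg.alpha, adjust=cfg.adjust,
            size_range=(float(pure_cov["size_cm"].min()),
                        float(pure_cov["size_cm"].max())),
        )
        report["tables"].append(
            _write(dfield.landmarks, cfg.out_dir,
                   "deformation_species.csv")
        )
        morpho_summary = {
            "n_aligned": len(gpa.shapes),
            "gpa_iterations": gpa.iterations,
            "species_deformation_significant_landmarks": int(
                dfield.landmarks["significant"].sum()
            ),
            "at_size": round(at_size, 4),
        }
        hyb_env_counts = hybrids["env"].value_counts()
        hybrids = hybrids[
            hybrids["env"].isin(hyb_env_counts[hyb_env_counts >= 5].index)
        ]
        if len(hybrids) >= 8:
            hyb_cov = hybrids[["id", "env", "size_cm", "h"]]
            hst = morpho.hybrid_shape_test(
                models, coords[coords["id"].isin(set(hybrids["id"]))],
                hyb_cov,
            )
            report["tables"].append(
                _write(hst.displacement, cfg.out_dir,
                       "hybrid_shape_displacement.csv")
            )
            n_reject = sum(
                1 for f in hst.deviation_models.values()
                if f.f_pvalue < cfg.alpha
            )
            morpho_summary["hybrid_shape"] = {
                "n_hybrids": len(hyb_cov),
                "n_coordinates_rejecting_additivity": n_reject,
                "n_coordinates_tested": len(hst.deviation_models),
            }
        report["stages"]["morpho"] = morpho_summary
        logger.info("morpho: %d shapes aligned in %d iterations",
                    len(gpa.shapes), gpa.iterations)

    # ----- diet ------------------------------------------------------------
    if cfg.stages.get("diet", True):
        vac = analysis.dropna(subset=["h"])
        vac_fit = None
        try:
            vac_fit = diet_mod.fit_vacuity_model(vac)
            report["tables"].append(
                _write(vac_fit.params.reset_index(names="term"),
                       cfg.out_dir, "vacuity_model.csv")
            )
            report["tables"].append(
                _write(vac_fit.lr_tests, cfg.out_dir, "vacuity_lr_tests.csv")
            )
        except diet_mod.DietEstimationError as exc:
            logger.warning("diet: vacuity model skipped: %s", exc)

        diet_summary: dict[str, Any] = {}
        if len(prey):
            classes = diet_mod.classify_diet_table(prey)
            merged = classes.merge(
                analysis[["id", "genomic_class", "zone", "season",
                          "size_cm"]],
                on="id", how="left",
            ).rename(columns={"genomic_class": "group", "zone": "env"})
            n_nodet = int((merged["diet_class"] ==
                           diet_mod.NO_DETECTION).sum())
            try:
                fi = diet_mod.feeding_index_pca(prey)
                fi_table = fi.scores.reset_index()
                fi_table.columns = ["id", "feeding_index"]
                report["tables"].append(
                    _write(fi_table, cfg.out_dir, "feeding_index.csv")
                )
                diet_summary["explained_inertia_pct"] = round(
                    100.0 * fi.explained_inertia, 3
                )
            except diet_mod.DietEstimationError as exc:
                logger.warning("diet: feeding index skipped: %s", exc)
            report["tables"].append(
                _write(merged, cfg.out_dir, "diet_classes.csv")
            )
            report["tables"].append(
                _write(
                    diet_mod.class_proportions(merged, by=("group", "env")),
                    cfg.out_dir, "diet_class_proportions.csv",
                )
            )
            try:
                mfit = diet_mod.fit_diet_multinomial(
                    merged.dropna(subset=["group", "env", "season",
                                          "size_cm"]).rename(
                        columns={"size_cm": "size"}
                    ),
                    terms=("C(season)", "C(env)", "C(group)", "size"),
                )
                report["tables"].append(
                    _write(mfit.params, cfg.out_dir,
                           "diet_multinomial_coefficients.csv")
                )
                report["tables"].append(
                    _write(mfit.lr_tests, cfg.out_dir,
                           "diet_multinomial_lr_tests.csv")
                )
                diet_summary["multinomial_terms"] = {
                    r["term"]: round(r["lr_chi2"], 4)
                    for _, r in mfit.lr_tests.iterrows()
                }
            except diet_mod.DietEstimationError as exc:
                logger.warning("diet: multinomial skipped: %s", exc)
            diet_summary["n_prey_rows"] = len(prey)
            diet_summary["n_no_detection"] = n_nodet
        report["stages"]["diet"] = diet_summary
        logger.info("diet: %d prey rows", len(prey))

    # ----- report ----------------------------------------------------------
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    with open(os.path.join(cfg.out_dir, "report.txt"), "w") as fh:
        fh.write(render_report(report))
    return report


def render_report(report: dict[str, Any]) -> str:
    # canonicalise ordering and numeric types so regeneration from the
    # emitted JSON is byte-identical
    report = json.loads(json.dumps(report, sort_keys=True, default=float))
    lines = [
        "hybeco run report",
        "=================",
        f"package version: {report['provenance']['package_version']}",
        f"seed: {report['provenance']['seed']}",
        f"config sha256: {report['provenance']['config_sha256']}",
        "",
    ]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    lines.append("tables:")
    for t in report["tables"]:
        lines.append(f"  - {t}")
    lines.append("")
    return "\n".join(lines)
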