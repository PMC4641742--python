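"""Synthetic hybrid-zone datasets with known ground truth.

Generates the four linked inputs of the analysis pipeline — codominant
genotypes (Genepop), per-individual covariates, 21-landmark shapes (TPS) and
a prey presence/absence matrix — from a single seeded configuration, plus a
truth table holding the generating parameters per individual.

Generative model
----------------
* genotypes: each gene copy of an individual with ancestry ``h`` is drawn
  from the mixture ``h * p_Pt + (1 - h) * p_Cn`` — the same per-allele model
  the ML hybrid-index estimator assumes (well-specified case by design).
* mtDNA: species Pt with probability ``h``.
* size: von-Bertalanffy saturating growth in age with species-specific
  asymptote and rate (hybrids interpolate by h), plus an additive zone
  effect and multiplicative log-normal noise.
* weight: ``K_true(size, sp, zone) * size^3`` mg with log-normal noise;
  hybrids receive ``heterosis_delta`` on top of the h-mixture of the
  parental K surfaces (0 = strict additivity).
* landmarks: species mean shape (hybrid mean = h-interpolation of the two
  parental shapes) + allometric drift * (size - reference size) + zone
  deformation + isotropic Gaussian noise.
* feces presence: Bernoulli from a logistic model on (h, season, size, env);
  prey detections Bernoulli from per-(species-group, zone) profiles,
  conditioned on feces presence.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
import yaml

from hybeco import genetics
from hybeco.genetics import CN, PT, HYBRID, GenotypeTable, AlleleFrequencyProfile

SEASONS = ("spring", "summer", "autumn")

# 21-landmark fish-outline template in digitising units (arbitrary constants:
# snout, dorsal profile, caudal peduncle, ventral profile, fin insertions,
# eye and operculum). Roughly 100 units long, 30 deep.
LANDMARK_TEMPLATE = np.array(
    [
        [0.0, 0.0],      # 1  snout tip
        [6.0, 6.0],      # 2  top of head
        [18.0, 10.0],    # 3  nape
        [38.0, 14.0],    # 4  anterior dorsal-fin insertion
        [52.0, 13.0],    # 5  posterior dorsal-fin insertion
        [70.0, 8.0],     # 6  dorsal caudal peduncle
        [84.0, 5.0],     # 7  upper caudal-fin insertion
        [88.0, 0.0],     # 8  caudal midpoint
        [84.0, -5.0],    # 9  lower caudal-fin insertion
        [70.0, -7.0],    # 10 ventral caudal peduncle
        [58.0, -9.0],    # 11 anal-fin posterior insertion
        [48.0, -11.0],   # 12 anal-fin anterior insertion
        [34.0, -13.0],   # 13 pelvic-fin insertion
        [20.0, -11.0],   # 14 pectoral-fin insertion
        [10.0, -7.0],    # 15 lower operculum
        [4.0, -3.0],     # 16 lower jaw
        [8.0, 1.0],      # 17 eye centre
        [12.0, 4.0],     # 18 upper operculum edge
        [14.0, -2.0],    # 19 posterior operculum
        [30.0, 2.0],     # 20 midbody lateral line
        [60.0, 0.0],     # 21 posterior lateral line
    ]
)

# Direction of the Cn -> Pt mean-shape difference (Pt more slender, longer
# caudal region): a vertical compression plus slight posterior elongation.
_y = LANDMARK_TEMPLATE[:, 1]
_x = LANDMARK_TEMPLATE[:, 0]
SPECIES_SHAPE_AXIS = np.column_stack(
    [0.03 * (_x - _x.mean()), -0.12 * _y]
)


def default_zones() -> list[dict[str, Any]]:
    return [
        {"name": "reference", "size_effect": 0.0, "k_effect": 0.0,
         "shape_scale": 0.0, "stations": ["ref_a", "ref_b"]},
        {"name": "ardeche", "size_effect": -1.0, "k_effect": -0.3,
         "shape_scale": 0.5, "stations": ["ard_up", "ard_down"]},
        {"name": "durance", "size_effect": -2.0, "k_effect": -0.6,
         "shape_scale": 1.0, "stations": ["dur_up", "dur_down"]},
    ]


def default_growth() -> dict[str, Any]:
    return {
        "age_range": [1, 8],
        "l_inf": {CN: 40.0, PT: 22.0},
        "rate": {CN: 0.25, PT: 0.40},
        "size_log_sd": 0.08,
    }


def default_k_surface() -> dict[str, Any]:
    # K_true = base[sp] + c1*(size-ref) + c2*(size-ref)^2 + zone k_effect
    return {
        "base": {CN: 10.5, PT: 9.0},
        "poly": {CN: [-0.05, 0.003], PT: [-0.08, 0.004]},
        "reference_size": 13.0,
        "k_log_sd": 0.05,
    }


def default_vacuity_coefs() -> dict[str, float]:
    # logit P(feces present) = intercept + h + size + season + env (+ h:...)
    return {
        "intercept": 0.8,
        "h": 0.4,
        "size": 0.02,
        "season_summer": -0.3,
        "season_autumn": -0.1,
        "env_ardeche": 0.2,
        "env_durance": -0.2,
        "h_size": 0.0,
        "h_season_summer": 0.0,
        "h_season_autumn": 0.0,
        "h_env_ardeche": 0.0,
        "h_env_durance": 0.0,
    }


DEFAULT_PREY_ITEMS = (
    "diatoms", "Diptera", "Mollusca", "Malacostraca",
    "Ephemeroptera", "Trichoptera", "Oligochaeta", "Copepoda",
)
DEFAULT_PREY_GROUPS = ("diatom",) + ("invertebrate",) * 7


def default_diet_profiles() -> dict[str, list[float]]:
    """Per-(species group) detection probabilities over the 8 items.

    Cn leans on diatoms, Pt on invertebrates; hybrids intermediate. A zone
    modifier is applied at draw time.
    """
    return {
        CN: [0.85, 0.25, 0.15, 0.10, 0.20, 0.15, 0.10, 0.10],
        PT: [0.30, 0.60, 0.40, 0.30, 0.50, 0.40, 0.25, 0.20],
        HYBRID: [0.55, 0.45, 0.30, 0.20, 0.35, 0.30, 0.18, 0.15],
    }


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic hybrid-zone dataset."""

    n_loci: int = 41
    n_alleles_per_locus: int = 4
    divergence: float = 0.8
    n_cn: int = 100
    n_pt: int = 100
    n_hybrid: int = 60
    h_distribution: dict[str, Any] = field(
        default_factory=lambda: {"name": "beta", "a": 1.5, "b": 1.5}
    )
    zones: list[dict[str, Any]] = field(default_factory=default_zones)
    growth: dict[str, Any] = field(default_factory=default_growth)
    k_surface: dict[str, Any] = field(default_factory=default_k_surface)
    heterosis_delta: float = 0.0
    allometry_scale: dict[str, float] = field(
        default_factory=lambda: {CN: 0.30, PT: 0.15}
    )
    species_shape_scale: float = 1.0
    landmark_sd: float = 0.15
    vacuity_coefs: dict[str, float] = field(
        default_factory=default_vacuity_coefs
    )
    diet_profiles: dict[str, list[float]] = field(
        default_factory=default_diet_profiles
    )
    prey_items: tuple[str, ...] = DEFAULT_PREY_ITEMS
    prey_groups: tuple[str, ...] = DEFAULT_PREY_GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError(
                f"divergence must be in [0, 1], got {self.divergence}"
            )
        if self.n_alleles_per_locus < 2:
            raise ValueError("n_alleles_per_locus must be >= 2")
        for n, label in ((self.n_cn, "n_cn"), (self.n_pt, "n_pt"),
                         (self.n_hybrid, "n_hybrid")):
            if n < 0:
                raise ValueError(f"{label} must be >= 0")
        for sp, probs in self.diet_profiles.items():
            arr = np.asarray(probs, dtype=float)
            if arr.shape != (len(self.prey_items),):
                raise ValueError(
                    f"diet profile for {sp!r} must have "
                    f"{len(self.prey_items)} entries"
                )
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"diet profile for {sp!r} outside [0, 1]")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        base = cls()
        merged: dict[str, Any] = {}
        for name in known:
            if name in d:
                default = getattr(base, name)
                value = d[name]
                if isinstance(default, dict) and isinstance(value, dict) \
                        and name not in ("h_distribution", "diet_profiles"):
                    new = copy.deepcopy(default)
                    for k, v in value.items():
                        if isinstance(v, dict) and isinstance(new.get(k), dict):
                            new[k].update(v)
                        else:
                            new[k] = v
                    merged[name] = new
                elif name in ("prey_items", "prey_groups"):
                    merged[name] = tuple(value)
                else:
                    merged[name] = value
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["prey_items"] = list(self.prey_items)
        d["prey_groups"] = list(self.prey_groups)
        return d


@dataclass
class SyntheticDataset:
    """All simulated tables plus the generating truth."""

    covariates: pd.DataFrame        # id, station, zone, season, species,
                                    # mtdna, age, size_cm, weight_mg, feces
    genotypes: GenotypeTable
    landmarks: dict[str, np.ndarray]  # id -> (21, 2)
    prey: pd.DataFrame              # id + 8 binary item columns (feces only)
    truth: pd.DataFrame             # id, true_h, true_species, zone, station
    freqs_true: dict[str, dict[str, np.ndarray]]
    config: SimulationConfig

    def write(self, out_dir: str) -> dict[str, str]:
        """Write all tables as plain-text files; returns the path map."""
        os.makedirs(out_dir, exist_ok=True)
        from hybeco.morpho import write_tps

        paths = {
            "genotypes": os.path.join(out_dir, "genotypes.gen"),
            "covariates": os.path.join(out_dir, "covariates.csv"),
            "landmarks": os.path.join(out_dir, "landmarks.tps"),
            "prey": os.path.join(out_dir, "prey.csv"),
            "truth": os.path.join(out_dir, "truth.csv"),
            "config": os.path.join(out_dir, "sim_config.yaml"),
        }
        genetics.write_genepop(self.genotypes, paths["genotypes"])
        self.covariates.to_csv(paths["covariates"], index=False,
                               float_format="%.10g")
        write_tps(self.landmarks, paths["landmarks"])
        self.prey.to_csv(paths["prey"], index=False)
        self.truth.to_csv(paths["truth"], index=False, float_format="%.10g")
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)
        return paths


def gen_allele_frequencies(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, dict[str, np.ndarray]]:
    """Parental allele-frequency vectors per locus.

    Allele 0 of each locus is the diagnostic one: its Cn - Pt frequency
    differential equals ``cfg.divergence`` exactly; the remaining mass is
    spread over the other alleles with shared Dirichlet weights, so no other
    allele can be more divergent. divergence=1 yields disjoint support.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    d = cfg.divergence
    k = cfg.n_alleles_per_locus
    out: dict[str, dict[str, np.ndarray]] = {}
    for j in range(cfg.n_loci):
        centre = rng.uniform(d / 2.0, 1.0 - d / 2.0)
        p0_cn = centre + d / 2.0
        p0_pt = centre - d / 2.0
        if k == 2:
            weights = np.array([1.0])
        else:
            weights = rng.dirichlet(np.full(k - 1, 2.0))
        p_cn = np.concatenate([[p0_cn], (1.0 - p0_cn) * weights])
        p_pt = np.concatenate([[p0_pt], (1.0 - p0_pt) * weights])
        out[f"L{j + 1:03d}"] = {CN: p_cn, PT: p_pt}
    return out


def _draw_h(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    spec = cfg.h_distribution
    name = spec.get("name", "beta")
    if name == "beta":
        return rng.beta(spec.get("a", 1.5), spec.get("b", 1.5), size=n)
    if name == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    if name == "point":
        return np.full(n, float(spec["value"]))
    raise ValueError(f"unknown h_distribution {name!r}")


def _interp(a: float, b: float, h: float) -> float:
    return (1.0 - h) * a + h * b


def true_k(
    cfg: SimulationConfig, size: float, h: float, zone_k_effect: float
) -> float:
    """Noise-free condition surface; hybrids are the h-mixture + heterosis."""
    ks = cfg.k_surface
    s = size - ks["reference_size"]

    def pure(sp: str) -> float:
        c1, c2 = ks["poly"][sp]
        return ks["base"][sp] + c1 * s + c2 * s * s + zone_k_effect

    k = _interp(pure(CN), pure(PT), h)
    if 0.0 < h < 1.0:
        k += cfg.heterosis_delta
    return k


def mean_shape(cfg: SimulationConfig, h: float, size: float,
               zone_shape_scale: float) -> np.ndarray:
    """Noise-free landmark configuration for ancestry h at a given size."""
    ref_size = cfg.k_surface["reference_size"]
    axis = cfg.species_shape_scale * SPECIES_SHAPE_AXIS
    cn_shape = LANDMARK_TEMPLATE - 0.5 * axis
    pt_shape = LANDMARK_TEMPLATE + 0.5 * axis
    base = (1.0 - h) * cn_shape + h * pt_shape
    # allometric vertical deepening, stronger in Cn
    slope = _interp(cfg.allometry_scale[CN], cfg.allometry_scale[PT], h)
    allo = np.zeros_like(base)
    allo[:, 1] = 0.01 * slope * LANDMARK_TEMPLATE[:, 1]
    # zone deformation: mild dorso-ventral compression
    zone_def = np.zeros_like(base)
    zone_def[:, 1] = -0.01 * zone_shape_scale * LANDMARK_TEMPLATE[:, 1]
    return base + allo * (size - ref_size) + zone_def


def gen_individuals(
    cfg: SimulationConfig,
    freqs: dict[str, dict[str, np.ndarray]] | None = None,
    include: tuple[str, ...] = ("genotypes", "landmarks", "prey"),
) -> SyntheticDataset:
    """Draw a complete dataset under the configured generative model.

    ``include`` selects which heavy blocks to generate; covariates and truth
    are always produced. Dropping a block does not perturb the remaining
    draws for a given seed only when the same blocks are dropped — the
    determinism contract is per (config, seed, include).
    """
    rng = np.random.default_rng(cfg.seed)
    with_geno = "genotypes" in include
    if freqs is None:
        freqs = gen_allele_frequencies(cfg, rng) if with_geno else {}
    loci = sorted(freqs)
    if with_geno and len(loci) != cfg.n_loci:
        raise ValueError(
            f"frequency profile has {len(loci)} loci, config says {cfg.n_loci}"
        )
    for locus, by_sp in freqs.items():
        for sp in (CN, PT):
            v = np.asarray(by_sp[sp])
            if abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
                raise ValueError(f"invalid frequency vector at {locus}/{sp}")

    groups = (
        [(CN, 0.0)] * cfg.n_cn
        + [(PT, 1.0)] * cfg.n_pt
        + [(HYBRID, np.nan)] * cfg.n_hybrid
    )
    n = len(groups)
    h_hyb = _draw_h(cfg, cfg.n_hybrid, rng)
    hyb_i = 0

    zones = cfg.zones
    syntopic = [z for z in zones if z["name"] != "reference"] or zones
    ks = cfg.k_surface
    gr = cfg.growth

    ids, stations, zone_names, seasons, species_lab, mtdnas = [], [], [], [], [], []
    ages, sizes, weights, feces_flags, hs = [], [], [], [], []
    geno_rows: list[list[tuple[str, str] | None]] = []
    pops: list[str] = []
    landmarks: dict[str, np.ndarray] = {}
    prey_rows: list[dict[str, Any]] = []

    vc = cfg.vacuity_coefs
    for idx, (group, h_fixed) in enumerate(groups):
        ind = f"ind{idx + 1:04d}"
        if group == HYBRID:
            h = float(h_hyb[hyb_i])
            hyb_i += 1
            zone = syntopic[rng.integers(len(syntopic))]
        else:
            h = h_fixed
            zone = zones[rng.integers(len(zones))]
        season = SEASONS[rng.integers(len(SEASONS))]
        station = zone["stations"][rng.integers(len(zone["stations"]))]

        # genotype: two independent copies per locus from the h-mixture
        if with_geno:
            row: list[tuple[str, str] | None] = []
            for locus in loci:
                p = h * freqs[locus][PT] + (1.0 - h) * freqs[locus][CN]
                a1, a2 = rng.choice(len(p), size=2, p=p / p.sum())
                row.append((str(a1 + 1), str(a2 + 1)))
            geno_rows.append(row)
        else:
            geno_rows.append([])
        pops.append(station)

        mtdna = PT if rng.random() < h else CN

        age = int(rng.integers(gr["age_range"][0], gr["age_range"][1] + 1))
        l_inf = _interp(gr["l_inf"][CN], gr["l_inf"][PT], h)
        rate = _interp(gr["rate"][CN], gr["rate"][PT], h)
        size = l_inf * (1.0 - np.exp(-rate * age)) + zone["size_effect"]
        size *= np.exp(rng.normal(0.0, gr["size_log_sd"]))
        size = max(size, 3.0)

        k = true_k(cfg, size, h, zone["k_effect"])
        weight = k * size**3 * np.exp(rng.normal(0.0, ks["k_log_sd"]))

        if "landmarks" in include:
            shape = mean_shape(cfg, h, size, zone["shape_scale"])
            shape = shape + rng.normal(0.0, cfg.landmark_sd, size=shape.shape)
            landmarks[ind] = shape

        env_name = zone["name"]
        logit = (
            vc["intercept"]
            + vc["h"] * h
            + vc["size"] * (size - ks["reference_size"])
            + vc.get(f"season_{season}", 0.0)
            + vc.get(f"env_{env_name}", 0.0)
            + vc["h_size"] * h * (size - ks["reference_size"])
            + vc.get(f"h_season_{season}", 0.0) * h
            + vc.get(f"h_env_{env_name}", 0.0) * h
        )
        feces = int(rng.random() < 1.0 / (1.0 + np.exp(-logit)))
        if feces and "prey" in include:
            profile = np.asarray(cfg.diet_profiles[group], dtype=float)
            # zones shift diet pressure: syntopic zones deplete diatoms a bit
            shift = 0.1 * zone["shape_scale"]
            probs = profile.copy()
            probs[0] = np.clip(probs[0] - shift, 0.0, 1.0)
            detections = (rng.random(len(probs)) < probs).astype(int)
            prey_rows.append(
                {"id": ind, **dict(zip(cfg.prey_items, detections))}
            )

        ids.append(ind)
        stations.append(station)
        zone_names.append(env_name)
        seasons.append(season)
        species_lab.append(group)
        mtdnas.append(mtdna)
        ages.append(age)
        sizes.append(float(size))
        weights.append(float(weight))
        feces_flags.append(feces)
        hs.append(h)

    covariates = pd.DataFrame(
        {
            "id": ids,
            "station": stations,
            "zone": zone_names,
            "season": seasons,
            "species": species_lab,
            "mtdna": mtdnas,
            "age": ages,
            "size_cm": sizes,
            "weight_mg": weights,
            "feces": feces_flags,
        }
    )
    truth = pd.DataFrame(
        {
            "id": ids,
            "true_h": hs,
            "true_species": species_lab,
            "zone": zone_names,
            "station": stations,
        }
    )
    genotypes = GenotypeTable(ids, loci, geno_rows, pops)
    prey = pd.DataFrame(prey_rows, columns=["id", *cfg.prey_items])
    if prey.empty:
        prey = pd.DataFrame(columns=["id", *cfg.prey_items])
    return SyntheticDataset(
        covariates=covariates,
        genotypes=genotypes,
        landmarks=landmarks,
        prey=prey,
        truth=truth,
        freqs_true=freqs,
        config=cfg,
    )


def true_frequency_profile(
    freqs: dict[str, dict[str, np.ndarray]]
) -> AlleleFrequencyProfile:
    """Wrap generator truth as a profile usable by the estimator (no smoothing)."""
    loci = sorted(freqs)
    table = {
        locus: {
            sp: {str(i + 1): float(p) for i, p in enumerate(freqs[locus][sp])}
            for sp in (CN, PT)
        }
        for locus in loci
    }
    return AlleleFrequencyProfile(
        loci=loci, freqs=table, panel_sizes={CN: 0, PT: 0}
    )
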