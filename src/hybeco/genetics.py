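"""Hybrid-index estimation and genomic classification.

Per-individual ancestry proportion ``h`` (0 = Cn, 1 = Pt) is estimated by
maximum likelihood under a per-allele mixture model: each gene copy carries
allele ``a`` with probability ``h * p_Pt(a) + (1 - h) * p_Cn(a)``, summed in
log over all non-missing gene copies. Nuclear classes use the closed ranges
[0, 0.086] (Cn) and [0.934, 1] (Pt); a nuclear-pure individual whose mtDNA
belongs to the other species is overridden to Hybrid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import skew

CN = "Cn"
PT = "Pt"
HYBRID = "Hybrid"

#: Closed upper bound of the pure-Cn nuclear range.
CN_UPPER = 0.086
#: Closed lower bound of the pure-Pt nuclear range.
PT_LOWER = 0.934

MISSING = None


class EstimationError(ValueError):
    """Raised when an individual carries no usable genetic information."""


@dataclass
class GenotypeTable:
    """Codominant multilocus genotypes: individuals x loci.

    ``genotypes[i][j]`` is an unordered pair of allele labels (tuple) or
    ``None`` for missing. Population labels are parallel to individuals.
    """

    individuals: list[str]
    loci: list[str]
    genotypes: list[list[tuple[str, str] | None]]
    populations: list[str]

    def __post_init__(self) -> None:
        n, p = len(self.individuals), len(self.loci)
        if len(self.genotypes) != n:
            raise ValueError("genotype rows do not match individuals")
        if any(len(row) != p for row in self.genotypes):
            raise ValueError("genotype row length does not match loci")
        if len(self.populations) != n:
            raise ValueError("population labels do not match individuals")

    def genotype(self, individual: str, locus: str) -> tuple[str, str] | None:
        i = self.individuals.index(individual)
        j = self.loci.index(locus)
        return self.genotypes[i][j]

    def subset(self, individuals: Sequence[str]) -> "GenotypeTable":
        idx = [self.individuals.index(ind) for ind in individuals]
        return GenotypeTable(
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            genotypes=[self.genotypes[i] for i in idx],
            populations=[self.populations[i] for i in idx],
        )

    def alleles_at(self, locus: str) -> set[str]:
        j = self.loci.index(locus)
        out: set[str] = set()
        for row in self.genotypes:
            g = row[j]
            if g is not None:
                out.update(g)
        return out


@dataclass
class AlleleFrequencyProfile:
    """Smoothed parental allele frequencies per locus and species.

    ``freqs[locus][species][allele]`` with a pseudo-count floor so that no
    allele observed anywhere in the data has zero parental frequency.
    """

    loci: list[str]
    freqs: dict[str, dict[str, dict[str, float]]]
    panel_sizes: dict[str, int]
    dropped_loci: list[str] = field(default_factory=list)

    def frequencies(self, locus: str, species: str) -> dict[str, float]:
        return self.freqs[locus][species]


@dataclass
class HybridIndexEstimate:
    individual: str
    h: float
    log_likelihood: float
    n_loci_used: int
    per_locus_loglik: dict[str, float]


@dataclass(frozen=True)
class GenomicClass:
    label: str  # Cn | Pt | Hybrid
    reason: str  # nuclear_range | mtDNA_discordance


def estimate_allele_frequencies(
    geno: GenotypeTable,
    reference_pops: Mapping[str, Sequence[str]],
    allele_universe: Mapping[str, Iterable[str]] | None = None,
) -> AlleleFrequencyProfile:
    """Estimate per-species allele frequencies from reference panels.

    ``reference_pops`` maps species label (Cn/Pt) to population labels that
    define its panel. Frequencies are smoothed with a per-allele pseudo-count
    eps = 1/(2*n_typed + 1):
    ``p(a) = (count(a) + eps) / (2*n_typed + eps*n_alleles)``.

    The allele universe per locus defaults to every allele observed anywhere
    in ``geno`` (so alleles private to non-panel individuals never receive a
    zero frequency). Loci with no panel data for either species are dropped
    and reported in ``dropped_loci``.
    """
    for species in (CN, PT):
        pops = set(reference_pops.get(species, ()))
        if not any(p in pops for p in geno.populations):
            raise ValueError(
                f"no reference individuals for species {species!r}; "
                f"populations requested: {sorted(pops)}"
            )

    panel_rows = {
        species: [
            i
            for i, pop in enumerate(geno.populations)
            if pop in set(reference_pops[species])
        ]
        for species in (CN, PT)
    }

    freqs: dict[str, dict[str, dict[str, float]]] = {}
    kept_loci: list[str] = []
    dropped: list[str] = []
    for j, locus in enumerate(geno.loci):
        universe = (
            set(allele_universe[locus])
            if allele_universe is not None
            else geno.alleles_at(locus)
        )
        if not universe:
            dropped.append(locus)
            continue
        by_species: dict[str, dict[str, float]] = {}
        ok = True
        for species in (CN, PT):
            counts: dict[str, float] = {a: 0.0 for a in sorted(universe)}
            n_typed = 0
            for i in panel_rows[species]:
                g = geno.genotypes[i][j]
                if g is None:
                    continue
                n_typed += 1
                for a in g:
                    if a not in counts:  # panel allele outside stated universe
                        counts[a] = 0.0
                    counts[a] += 1.0
            if n_typed == 0:
                ok = False
                break
            eps = 1.0 / (2 * n_typed + 1)
            denom = 2 * n_typed + eps * len(counts)
            by_species[species] = {
                a: (c + eps) / denom for a, c in counts.items()
            }
        if not ok:
            dropped.append(locus)
            continue
        kept_loci.append(locus)
        freqs[locus] = by_species

    return AlleleFrequencyProfile(
        loci=kept_loci,
        freqs=freqs,
        panel_sizes={sp: len(panel_rows[sp]) for sp in (CN, PT)},
        dropped_loci=dropped,
    )


def _copy_probs(
    genotype_row: Sequence[tuple[str, str] | None],
    loci: Sequence[str],
    freqs: AlleleFrequencyProfile,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per gene copy (p_Cn(a), p_Pt(a)) arrays and the loci contributing."""
    p_cn: list[float] = []
    p_pt: list[float] = []
    used: list[str] = []
    fmap = freqs.freqs
    for locus, g in zip(loci, genotype_row):
        if g is None or locus not in fmap:
            continue
        fc = fmap[locus][CN]
        fp = fmap[locus][PT]
        for a in g:
            if a not in fc or a not in fp:
                # allele outside the smoothed universe: floor at the minimum
                # observed smoothed frequency so the copy stays informative
                p_cn.append(min(fc.values()))
                p_pt.append(min(fp.values()))
            else:
                p_cn.append(fc[a])
                p_pt.append(fp[a])
        used.append(locus)
    return np.asarray(p_cn), np.asarray(p_pt), used


def hybrid_index_loglik(
    h: float,
    p_cn: np.ndarray,
    p_pt: np.ndarray,
) -> float:
    """Log-likelihood of ancestry h over independent gene copies."""
    with np.errstate(divide="ignore"):
        return float(np.log(h * p_pt + (1.0 - h) * p_cn).sum())


def hybrid_index_ml(
    individual: str,
    genotype_row: Sequence[tuple[str, str] | None],
    loci: Sequence[str],
    freqs: AlleleFrequencyProfile,
) -> HybridIndexEstimate:
    """Maximum-likelihood hybrid index on [0, 1].

    The per-copy log-likelihood is a sum of logs of functions linear in h,
    hence concave; a bounded Brent search plus explicit endpoint comparison
    returns the global optimum.
    """
    p_cn, p_pt, used = _copy_probs(genotype_row, loci, freqs)
    if p_cn.size == 0:
        raise EstimationError(
            f"individual {individual!r}: all loci missing or unscored"
        )

    def neg(h: float) -> float:
        return -hybrid_index_loglik(h, p_cn, p_pt)

    res = minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    candidates = [(float(res.x), -float(res.fun))]
    for h0 in (0.0, 1.0):
        candidates.append((h0, hybrid_index_loglik(h0, p_cn, p_pt)))
    h_hat, ll = max(candidates, key=lambda t: t[1])
    h_hat = min(max(h_hat, 0.0), 1.0)

    per_locus: dict[str, float] = {}
    k = 0
    for locus, g in zip(loci, genotype_row):
        if g is None or locus not in freqs.freqs:
            continue
        n_copies = len(g)
        per_locus[locus] = float(
            np.log(h_hat * p_pt[k:k + n_copies]
                   + (1 - h_hat) * p_cn[k:k + n_copies]).sum()
        )
        k += n_copies
    return HybridIndexEstimate(
        individual=individual,
        h=h_hat,
        log_likelihood=ll,
        n_loci_used=len(used),
        per_locus_loglik=per_locus,
    )


def estimate_hybrid_indices(
    geno: GenotypeTable, freqs: AlleleFrequencyProfile
) -> pd.DataFrame:
    """Hybrid index for every individual of a table; one row each."""
    rows = []
    for i, ind in enumerate(geno.individuals):
        est = hybrid_index_ml(ind, geno.genotypes[i], geno.loci, freqs)
        rows.append(
            {
                "id": ind,
                "population": geno.populations[i],
                "h": est.h,
                "log_likelihood": est.log_likelihood,
                "n_loci_used": est.n_loci_used,
            }
        )
    return pd.DataFrame(rows)


def classify_genomic(
    h: float,
    mtdna: str | None,
    cn_upper: float = CN_UPPER,
    pt_lower: float = PT_LOWER,
) -> GenomicClass:
    """Three-class genomic label with the mtDNA-discordance override.

    Closed ranges: [0, cn_upper] -> Cn, [pt_lower, 1] -> Pt, the open
    interval between -> Hybrid. A nuclear-pure label discordant with the
    mtDNA species is overridden to Hybrid; missing mtDNA skips the override.
    """
    if math.isnan(h) if isinstance(h, float) else False:
        raise ValueError("h is NaN")
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"h = {h} outside [0, 1]")
    if h <= cn_upper:
        nuclear = CN
    elif h >= pt_lower:
        nuclear = PT
    else:
        nuclear = HYBRID
    if nuclear in (CN, PT) and mtdna in (CN, PT) and mtdna != nuclear:
        return GenomicClass(label=HYBRID, reason="mtDNA_discordance")
    return GenomicClass(label=nuclear, reason="nuclear_range")


def summarize_population(
    classes: Sequence[str],
    h_values: Sequence[float],
    stations: Sequence[str],
) -> pd.DataFrame:
    """Per-station class percentages, h quartiles and skewness direction."""
    df = pd.DataFrame(
        {"station": stations, "label": classes, "h": h_values}
    )
    rows = []
    for station, grp in df.groupby("station", sort=True):
        n = len(grp)
        counts = grp["label"].value_counts()
        q1, q2, q3 = np.percentile(grp["h"], [25, 50, 75])
        g = skew(grp["h"]) if n > 2 and grp["h"].std() > 1e-12 else 0.0
        rows.append(
            {
                "station": station,
                "n": n,
                "pct_cn": 100.0 * counts.get(CN, 0) / n,
                "pct_pt": 100.0 * counts.get(PT, 0) / n,
                "pct_hybrid": 100.0 * counts.get(HYBRID, 0) / n,
                "h_q25": q1,
                "h_median": q2,
                "h_q75": q3,
                "h_skew": "high" if g > 0 else ("low" if g < 0 else "none"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genepop I/O (2- and 3-digit allele coding) and delimited dialects
# ---------------------------------------------------------------------------

def read_genepop(path: str) -> GenotypeTable:
    """Read a Genepop file; auto-detects 2- vs 3-digit allele coding.

    Populations are named pop1, pop2, ... in file order unless the first
    individual name of a pop block carries a label (the conventional usage
    of the name before the comma is kept as the individual id; population
    labels here are positional).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"{path}: empty Genepop file")
    # line 0 is the title
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names: one per line, or comma-separated
        for name in lines[i].split(","):
            name = name.strip()
            if name:
                loci.append(name)
        i += 1
    if not loci:
        raise ValueError(f"{path}: no locus names before first 'pop'")

    individuals: list[str] = []
    genotypes: list[list[tuple[str, str] | None]] = []
    populations: list[str] = []
    pop_idx = 0
    digits: int | None = None
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ValueError(f"{path}: malformed individual line: {line!r}")
        name, geno_str = line.split(",", 1)
        fields = geno_str.split()
        if len(fields) != len(loci):
            raise ValueError(
                f"{path}: individual {name.strip()!r} has {len(fields)} "
                f"genotypes for {len(loci)} loci"
            )
        row: list[tuple[str, str] | None] = []
        for tok in fields:
            if digits is None:
                if len(tok) == 4:
                    digits = 2
                elif len(tok) == 6:
                    digits = 3
                else:
                    raise ValueError(
                        f"{path}: cannot infer allele coding from {tok!r}"
                    )
            if len(tok) != 2 * digits:
                raise ValueError(f"{path}: genotype token {tok!r} has wrong width")
            a1, a2 = tok[:digits], tok[digits:]
            zero = "0" * digits
            if a1 == zero or a2 == zero:
                row.append(None)
            else:
                row.append((a1, a2))
        individuals.append(name.strip())
        genotypes.append(row)
        populations.append(f"pop{pop_idx}")
    return GenotypeTable(individuals, loci, genotypes, populations)


def write_genepop(
    table: GenotypeTable, path: str, title: str = "hybeco genotypes",
    digits: int = 3,
) -> None:
    """Write a Genepop file with one pop block per population label.

    Rows are grouped by population (first-appearance order) so each label
    yields a single contiguous block.
    """
    zero = "0" * digits
    pop_order = list(dict.fromkeys(table.populations))
    ordered = sorted(
        zip(table.individuals, table.populations, table.genotypes),
        key=lambda t: pop_order.index(t[1]),
    )
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        current_pop: str | None = None
        for ind, pop, row in ordered:
            if pop != current_pop:
                fh.write("pop\n")
                current_pop = pop
            toks = []
            for g in row:
                if g is None:
                    toks.append(zero + zero)
                else:
                    toks.append(
                        f"{int(g[0]):0{digits}d}{int(g[1]):0{digits}d}"
                    )
            fh.write(f"{ind}, " + " ".join(toks) + "\n")


def read_genotype_table(path: str, sep: str = ",") -> GenotypeTable:
    """Read a delimited long-format genotype table.

    Columns: id, population, locus, allele1, allele2 (empty alleles =
    missing).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"id", "population", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    loci = list(dict.fromkeys(df["locus"]))
    individuals = list(dict.fromkeys(df["id"]))
    pop_of = dict(zip(df["id"], df["population"]))
    cell: dict[tuple[str, str], tuple[str, str] | None] = {}
    for _, r in df.iterrows():
        if r["allele1"] == "" or r["allele2"] == "":
            cell[(r["id"], r["locus"])] = None
        else:
            cell[(r["id"], r["locus"])] = (r["allele1"], r["allele2"])
    genotypes = [
        [cell.get((ind, locus)) for locus in loci] for ind in individuals
    ]
    return GenotypeTable(
        individuals, loci, genotypes, [pop_of[i] for i in individuals]
    )


def read_mtdna(path: str, sep: str = ",") -> dict[str, str]:
    """Two-column table (id, mtdna) -> mapping; empty values mean missing."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if not {"id", "mtdna"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns id, mtdna")
    return {
        r["id"]: (r["mtdna"] if r["mtdna"] in (CN, PT) else None)
        for _, r in df.iterrows()
    }
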