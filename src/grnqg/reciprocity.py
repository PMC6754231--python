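"""Cross-trait allelic-effect ("reciprocity") analysis.

For every SNP the allelic effect on a trait is the difference between the
median phenotype of the alternate-allele strains and that of the
reference-allele strains (reference = parent-A / N2-like class, fixed across
traits so the signs of the two traits are comparable). A reciprocal genetic
architecture — variants that raise the requirement for one regulatory input
while relaxing the other — shows up as a negative correlation between the
two traits' allelic effects across the genome.

The pipeline order is fixed: allele-class-size filter -> LD pruning
(sliding-window greedy removal of one member of every pair with squared
genotype correlation above the threshold, PLINK indep-pairwise style) ->
effect computation -> single-pass z-score outlier exclusion (a marker is
dropped if |z| > cutoff in either trait; statistics are not recomputed
iteratively) -> Pearson correlation of the two effect columns, genome-wide
and per chromosome, plus a strain-level Spearman correlation of the raw
phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import MISSING, GenotypeMatrix, MarkerMap, PhenotypeTable
from .errors import ConfigurationError, DataError

__all__ = [
    "AllelicEffectTable",
    "ReciprocityReport",
    "per_snp_allelic_effect",
    "ld_prune",
    "zscore_outlier_filter",
    "cross_trait_correlation",
    "strain_level_correlation",
    "reciprocity_analysis",
]


@dataclass
class AllelicEffectTable:
    """Per-marker allelic effects for two traits.

    ``frame`` is indexed by marker id with columns chrom, bp, n_ref, n_alt,
    effect_trait1, effect_trait2, included (bool) and reason (exclusion
    reason: '', 'class_size', 'pruned', 'outlier').
    """

    frame: pd.DataFrame
    trait_names: tuple[str, str]

    def included(self) -> pd.DataFrame:
        return self.frame[self.frame["included"]]


@dataclass
class ReciprocityReport:
    genome_wide_r: float
    genome_wide_p: float
    n_markers: int
    per_chromosome: pd.DataFrame  # chrom, r, p, n (NaN where undefined)
    strain_spearman_rho: float | None = None
    strain_spearman_p: float | None = None
    n_strains: int | None = None
    stage_counts: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def per_snp_allelic_effect(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                           trait1: str, trait2: str, min_class_size: int = 3,
                           marker_map: MarkerMap | None = None) -> AllelicEffectTable:
    """Median-difference allelic effect per marker and trait.

    effect = median(phenotype | code-2 strains) - median(phenotype | code-0
    strains); heterozygote and missing calls are excluded from both classes.
    Markers where either class has fewer than ``min_class_size`` strains with
    phenotype are excluded with reason ``class_size``.
    """
    y1 = phenotypes.trait_vector(trait1, genotypes.strain_ids).to_numpy(float)
    y2 = phenotypes.trait_vector(trait2, genotypes.strain_ids).to_numpy(float)
    rows = []
    for j, mid in enumerate(genotypes.marker_ids):
        g = genotypes.values[:, j]
        row: dict = {"marker": mid, "n_ref": 0, "n_alt": 0,
                     "effect_trait1": np.nan, "effect_trait2": np.nan,
                     "included": False, "reason": "class_size"}
        effs = []
        counts = []
        for y in (y1, y2):
            ok = ~np.isnan(y)
            ref = y[ok & (g == 0)]
            alt = y[ok & (g == 2)]
            counts.append((ref.size, alt.size))
            if ref.size >= min_class_size and alt.size >= min_class_size:
                effs.append(float(np.median(alt) - np.median(ref)))
            else:
                effs.append(np.nan)
        row["n_ref"], row["n_alt"] = counts[0]
        if not np.isnan(effs).any():
            row.update(effect_trait1=effs[0], effect_trait2=effs[1],
                       included=True, reason="")
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("marker")
    if marker_map is not None:
        frame.insert(0, "chrom", marker_map.frame["chrom"].reindex(frame.index))
        frame.insert(1, "bp", marker_map.frame["bp"].reindex(frame.index))
    else:
        frame.insert(0, "chrom", "")
        frame.insert(1, "bp", np.arange(len(frame)))
    return AllelicEffectTable(frame, (trait1, trait2))


def _pairwise_r2(G: np.ndarray, a: int, b: int) -> float:
    ga, gb = G[:, a].astype(float), G[:, b].astype(float)
    ok = (G[:, a] != MISSING) & (G[:, b] != MISSING)
    if ok.sum() < 2:
        return 0.0
    ga, gb = ga[ok], gb[ok]
    if np.ptp(ga) == 0 or np.ptp(gb) == 0:
        return 0.0
    r = np.corrcoef(ga, gb)[0, 1]
    return float(r * r)


def ld_prune(genotypes: GenotypeMatrix, window_size: int = 50, step: int = 5,
             r2_threshold: float = 0.8) -> np.ndarray:
    """Sliding-window greedy LD pruning; returns retained marker indices.

    Within each window of ``window_size`` markers (advancing by ``step``),
    while any retained pair has squared genotype correlation above the
    threshold, the member of the worst pair with the lower MAF is removed
    (ties: the later map position). Markers must already be map-sorted.
    """
    if window_size < 2:
        raise ConfigurationError("window_size must be >= 2")
    if step < 1:
        raise ConfigurationError("step must be >= 1")
    m = genotypes.n_markers
    maf = genotypes.maf()
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        window = [j for j in range(start, min(start + window_size, m)) if keep[j]]
        while True:
            worst = None
            for ai in range(len(window)):
                for bi in range(ai + 1, len(window)):
                    a, b = window[ai], window[bi]
                    r2 = _pairwise_r2(genotypes.values, a, b)
                    if r2 > r2_threshold and (worst is None or r2 > worst[0]):
                        worst = (r2, a, b)
            if worst is None:
                break
            _, a, b = worst
            if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                drop = a
            else:
                drop = b
            keep[drop] = False
            window.remove(drop)
        if start + window_size >= m:
            break
        start += step
    return np.flatnonzero(keep)


def zscore_outlier_filter(table: AllelicEffectTable, cutoff: float = 1.96
                          ) -> AllelicEffectTable:
    """Single-pass z-score outlier exclusion on the included effects.

    z is computed per trait from the mean and sample standard deviation of
    that trait's currently included effects; a marker is excluded (reason
    ``outlier``) if |z| > cutoff in either trait. Statistics are not
    recomputed after removals — applying the filter twice may remove more.
    """
    frame = table.frame.copy()
    inc = frame["included"].to_numpy()
    if inc.sum() < 3:
        raise DataError("need >= 3 included markers for outlier filtering")
    drop = np.zeros(len(frame), dtype=bool)
    for col in ("effect_trait1", "effect_trait2"):
        e = frame.loc[inc, col].to_numpy(float)
        sd = e.std(ddof=1)
        if sd == 0:
            warnings.warn(f"zero variance in {col}; no outliers removable")
            continue
        z = (frame[col].to_numpy(float) - e.mean()) / sd
        drop |= inc & (np.abs(z) > cutoff)
    frame.loc[drop, "included"] = False
    frame.loc[drop, "reason"] = "outlier"
    return AllelicEffectTable(frame, table.trait_names)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cross_trait_correlation(table: AllelicEffectTable) -> ReciprocityReport:
    """Pearson correlation of the two traits' allelic effects, genome-wide
    and per chromosome (groups with < 3 markers reported as undefined)."""
    inc = table.included()
    if len(inc) < 3:
        raise DataError("fewer than 3 included markers; no correlation defined")
    r, p = _pearson(inc["effect_trait1"].to_numpy(float),
                    inc["effect_trait2"].to_numpy(float))
    rows = []
    for chrom, sub in inc.groupby("chrom", sort=False):
        if len(sub) >= 3:
            rc, pc = _pearson(sub["effect_trait1"].to_numpy(float),
                              sub["effect_trait2"].to_numpy(float))
        else:
            rc, pc = np.nan, np.nan
        rows.append({"chrom": chrom, "r": rc, "p": pc, "n": len(sub)})
    per_chrom = pd.DataFrame(rows)
    counts = {
        "raw": len(table.frame),
        "class_size_pass": int((table.frame["reason"] != "class_size").sum()),
        "after_prune": int((~table.frame["reason"].isin(["class_size", "pruned"])).sum()),
        "included": len(inc),
    }
    return ReciprocityReport(r, p, len(inc), per_chrom, stage_counts=counts)


def strain_level_correlation(phenotypes: PhenotypeTable, trait1: str, trait2: str
                             ) -> tuple[float, float]:
    """Spearman rho (average ranks for ties; t approximation for p) between
    two traits over strains phenotyped for both."""
    y1 = phenotypes.trait_vector(trait1)
    y2 = phenotypes.trait_vector(trait2).reindex(y1.index)
    ok = y1.notna() & y2.notna()
    if ok.sum() < 4:
        raise DataError("need >= 4 strains phenotyped for both traits")
    rho, p = stats.spearmanr(y1[ok], y2[ok])
    return float(rho), float(p)


def reciprocity_analysis(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                         phenotypes: PhenotypeTable, trait1: str, trait2: str,
                         window_size: int = 50, step: int = 5,
                         r2_threshold: float = 0.8, z_cutoff: float = 1.96,
                         min_class_size: int = 3
                         ) -> tuple[AllelicEffectTable, ReciprocityReport]:
    """Full chain: class-size filter -> LD prune -> effects -> outlier filter
    -> genome-wide / per-chromosome correlation + strain-level Spearman."""
    gm, mm = marker_map.sorted_by_position(genotypes)
    table = per_snp_allelic_effect(gm, phenotypes, trait1, trait2,
                                   min_class_size, mm)
    retained = set(np.asarray(ld_prune(gm, window_size, step, r2_threshold)))
    pruned_mask = np.array([j not in retained for j in range(gm.n_markers)])
    to_prune = pruned_mask & table.frame["included"].to_numpy().copy()
    table.frame.loc[to_prune, "included"] = False
    table.frame.loc[to_prune, "reason"] = "pruned"
    table = zscore_outlier_filter(table, z_cutoff)
    report = cross_trait_correlation(table)
    rho, p = strain_level_correlation(phenotypes, trait1, trait2)
    report.strain_spearman_rho = rho
    report.strain_spearman_p = p
    report.n_strains = int((phenotypes.values[trait1].notna()
                            & phenotypes.values[trait2].notna()).sum())
    report.config = {"window_size": window_size, "step": step,
                     "r2_threshold": r2_threshold, "z_cutoff": z_cutoff,
                     "min_class_size": min_class_size}
    return table, report
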