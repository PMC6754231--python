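"""Synthetic wild-isolate panels, recombinant inbred lines and penetrance
phenotypes.

The generator reproduces the statistical structure the downstream scans
assume rather than any particular genome:

* **Isolate panel** — a set of fully homozygous clonal strains drawn from one
  or more subpopulations. Marker allele frequencies follow the
  Balding–Nichols construction: per marker an ancestral frequency p is drawn,
  and each subpopulation receives a frequency from
  ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` where ``F`` is the differentiation
  parameter (F_ST). Genotypes are 0 or 2 before optional uniform genotyping
  error (0 <-> 2 flips) and missingness injection.
* **RILs** — a biparental cross followed by single-line selfing. Meiosis uses
  a Poisson crossover count per chromosome (mean = length in Morgans) with
  uniform placement, i.e. Haldane's model with no interference, matching the
  map function of the interval-mapping HMM. The F1 selfs once to give the F2,
  then each line selfs for a configurable number of further generations;
  residual heterozygotes are emitted as code 1.
* **Penetrance traits** — two correlated traits on the liability scale:
  liability = baseline + sum(QTL dosage x effect) + polygenic background +
  strain noise, pushed through a logistic link (clipped to
  [1e-6, 1 - 1e-6]) to give a per-strain penetrance, then observed as the
  mean over replicates of Binomial(embryos_per_replicate, penetrance)
  fractions — emulating scoring >= 500 arrested embryos per replicate for
  gut differentiation. The polygenic background is realised as many small
  genotype-borne effects so that kinship confounding is real and testable.
* **Trait on a tree** — tip values from a multivariate normal whose
  covariance is the Brownian-motion matrix with off-diagonal entries scaled
  by lambda (Pagel's transformation), for phylogenetic-signal recovery
  tests.

All draws come from ``numpy.random.default_rng(seed)``; identical seed and
configuration give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeMatrix, MarkerMap, PhenotypeTable
from .errors import ConfigurationError, DataError

__all__ = [
    "SimulationConfig",
    "QtlEffect",
    "TraitArchitecture",
    "simulate_isolate_panel",
    "simulate_ril_population",
    "simulate_phenotypes",
    "simulate_trait_on_tree",
    "bm_covariance",
]

_BP_PER_CM = 250_000  # physical spacing used when synthesising bp coordinates


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_strains: int
    chromosomes: tuple[tuple[str, float], ...] = (("I", 50.0), ("II", 50.0))
    markers_per_chromosome: int = 50
    n_subpopulations: int = 1
    fst: float = 0.0
    sample_missing_rate: float = 0.0
    genotyping_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigurationError("at least one chromosome required")
        if any(length < 0 for _, length in self.chromosomes):
            raise ConfigurationError("chromosome lengths must be >= 0 cM")
        if self.markers_per_chromosome < 2:
            raise ConfigurationError("need >= 2 markers per chromosome")
        if self.n_subpopulations < 1:
            raise ConfigurationError("n_subpopulations must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigurationError(f"fst must lie in [0, 1), got {self.fst}")
        for name in ("sample_missing_rate", "genotyping_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v}")


@dataclass(frozen=True)
class QtlEffect:
    chromosome: str
    position_cM: float
    effect_trait1: float  # liability units per allele copy
    effect_trait2: float


@dataclass(frozen=True)
class TraitArchitecture:
    """Two-trait liability architecture.

    ``polygenic_background = (n_loci, total_sd)`` spreads a background of the
    given total liability SD over that many randomly chosen markers, with
    independent weights per trait. ``strain_noise_sd`` is the non-genetic
    strain-level liability noise; replicate counts default to the study
    design of >= 500 embryos in each of two replicates.
    """

    baseline_liability: tuple[float, float] = (0.0, 0.0)
    qtls: tuple[QtlEffect, ...] = ()
    polygenic_background: tuple[int, float] = (0, 0.0)
    embryos_per_replicate: int = 500
    replicates: int = 2
    strain_noise_sd: float = 0.25
    liability_link: str = "logistic"
    trait_names: tuple[str, str] = ("trait1", "trait2")

    def __post_init__(self) -> None:
        if self.embryos_per_replicate < 1:
            raise ConfigurationError("embryos_per_replicate must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.polygenic_background[1] < 0:
            raise ConfigurationError("polygenic total_sd must be >= 0")
        if self.liability_link != "logistic":
            raise ConfigurationError("only the logistic link is implemented")


# ---------------------------------------------------------------------------
# isolate panel
# ---------------------------------------------------------------------------

def _synthesise_map(config: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    ids, chroms, bps, cms = [], [], [], []
    for name, length in config.chromosomes:
        pos = np.sort(rng.uniform(0.0, max(length, 1e-9), config.markers_per_chromosome))
        bp = np.maximum(1, np.round(pos * _BP_PER_CM)).astype(np.int64)
        bp = np.maximum.accumulate(bp) + np.arange(len(bp))  # strictly increasing
        for j, (p, b) in enumerate(zip(pos, bp)):
            ids.append(f"{name}:{int(b)}")
            chroms.append(name)
            bps.append(int(b))
            cms.append(float(p))
    return MarkerMap.from_arrays(ids, chroms, bps, cms)


def simulate_isolate_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, MarkerMap, np.ndarray]:
    """Simulate a homozygous multi-population isolate panel.

    Returns the genotype matrix (codes 0/2 plus injected missing), the
    synthesised marker map, and the per-strain subpopulation labels.
    """
    rng = np.random.default_rng(config.seed)
    marker_map = _synthesise_map(config, rng)
    m = len(marker_map.marker_ids)
    n = config.n_strains
    k = config.n_subpopulations

    ancestral = rng.uniform(0.05, 0.95, size=m)
    if config.fst == 0.0:
        subpop_freq = np.tile(ancestral, (k, 1))
    else:
        ratio = (1.0 - config.fst) / config.fst
        subpop_freq = rng.beta(ancestral * ratio, (1.0 - ancestral) * ratio, size=(k, m))

    labels = np.arange(n) % k
    p = subpop_freq[labels]  # (n, m)
    values = (2 * (rng.random((n, m)) < p)).astype(np.int8)

    if config.genotyping_error_rate > 0.0:
        flip = rng.random((n, m)) < config.genotyping_error_rate
        values = np.where(flip, 2 - values, values).astype(np.int8)
    if config.sample_missing_rate > 0.0:
        miss = rng.random((n, m)) < config.sample_missing_rate
        values = np.where(miss, MISSING, values).astype(np.int8)

    strains = [f"WI{i:04d}" for i in range(n)]
    return GenotypeMatrix(strains, marker_map.marker_ids, values), marker_map, labels


# ---------------------------------------------------------------------------
# RIL population
# ---------------------------------------------------------------------------

def _meiosis(hap1: np.ndarray, hap2: np.ndarray, chrom_slices: list[slice],
             chrom_lengths: list[float], pos_cm: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from a diploid (n, m) haplotype pair.

    Crossovers per chromosome ~ Poisson(length in Morgans), placed uniformly;
    the phase at a marker is the starting phase plus the number of crossovers
    to its left, mod 2 (Haldane, no interference).
    """
    n = hap1.shape[0]
    gamete = np.empty_like(hap1)
    for sl, length in zip(chrom_slices, chrom_lengths):
        pos = pos_cm[sl]
        counts = rng.poisson(length / 100.0, size=n)
        kmax = int(counts.max()) if n else 0
        start = rng.integers(0, 2, size=n)
        if kmax == 0:
            phase = np.broadcast_to(start[:, None], (n, pos.size))
        else:
            xo = rng.uniform(0.0, max(length, 1e-12), size=(n, kmax))
            xo[np.arange(kmax)[None, :] >= counts[:, None]] = np.inf
            n_left = (xo[:, :, None] < pos[None, None, :]).sum(axis=1)
            phase = (start[:, None] + n_left) % 2
        seg = np.where(phase == 0, hap1[:, sl], hap2[:, sl])
        gamete[:, sl] = seg
    return gamete


def simulate_ril_population(parent_a: np.ndarray, parent_b: np.ndarray,
                            marker_map: MarkerMap, n_rils: int,
                            selfing_generations: int = 10,
                            seed: int | None = 0) -> GenotypeMatrix:
    """Simulate selfed RILs from a biparental cross.

    ``parent_a`` / ``parent_b`` are haploid allele vectors (one value per
    marker); parents must differ at every marker, so genotypes are reported
    in parental-origin codes: 0 = homozygous parent A, 2 = homozygous parent
    B, 1 = residual heterozygote. The F1 selfs once to give the F2 and each
    F2 line then selfs ``selfing_generations`` further times.
    """
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    m = len(marker_map.marker_ids)
    if parent_a.shape != (m,) or parent_b.shape != (m,):
        raise DataError("parent haplotypes must have one allele per map marker")
    if np.any(parent_a == parent_b):
        raise DataError("parents must be homozygous and distinct at every marker")
    if selfing_generations < 0:
        raise ConfigurationError("selfing_generations must be >= 0")

    rng = np.random.default_rng(seed)
    chroms = marker_map.chromosomes()
    pos_cm = marker_map.frame["cM"].to_numpy(float)
    if np.isnan(pos_cm).any():
        raise DataError("marker map needs genetic (cM) positions for meiosis")
    slices, lengths = [], []
    offset = 0
    for c in chroms:
        idx = marker_map.chrom_markers(c)
        if not np.array_equal(idx, np.arange(offset, offset + len(idx))):
            raise DataError("marker map must be sorted by chromosome and position")
        slices.append(slice(offset, offset + len(idx)))
        lengths.append(float(pos_cm[idx].max() - pos_cm[idx].min()) if len(idx) else 0.0)
        offset += len(idx)

    # haplotypes in parental-origin space: 0 = from A, 1 = from B
    hap1 = np.zeros((n_rils, m), dtype=np.int8)  # F1 carries one A and one B copy
    hap2 = np.ones((n_rils, m), dtype=np.int8)
    for _ in range(1 + selfing_generations):  # F1 -> F2, then further selfing
        g1 = _meiosis(hap1, hap2, slices, lengths, pos_cm, rng)
        g2 = _meiosis(hap1, hap2, slices, lengths, pos_cm, rng)
        hap1, hap2 = g1, g2

    values = (hap1 + hap2).astype(np.int8)  # 0 = AA, 1 = het, 2 = BB
    strains = [f"RIL{i:04d}" for i in range(n_rils)]
    return GenotypeMatrix(strains, marker_map.marker_ids, values)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _nearest_marker(marker_map: MarkerMap, chromosome: str, position_cm: float) -> int:
    if chromosome not in marker_map.chromosomes():
        raise ConfigurationError(f"QTL on unknown chromosome {chromosome!r}")
    idx = marker_map.chrom_markers(chromosome)
    cm = marker_map.frame["cM"].to_numpy(float)[idx]
    return int(idx[np.argmin(np.abs(cm - position_cm))])


def simulate_phenotypes(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                        arch: TraitArchitecture, kinship_like_background: bool = True,
                        seed: int | None = 0) -> PhenotypeTable:
    """Simulate two penetrance traits on a genotyped panel.

    Per strain and trait: liability = baseline + QTL dosages x effects +
    polygenic background + strain noise; penetrance = logistic(liability);
    the observed value is the mean over replicates of binomial fractions.
    Missing genotype calls contribute the marker-mean dosage. When
    ``kinship_like_background`` is False the polygenic term is dropped even
    if the architecture specifies one.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_strains
    dosage = genotypes.values.astype(float)
    obs = genotypes.observed()
    col_mean = np.where(obs, dosage, np.nan)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(col_mean, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=1.0)
    dosage = np.where(obs, dosage, col_mean[None, :])

    effects = np.zeros((genotypes.n_markers, 2))
    for q in arch.qtls:
        j = _nearest_marker(marker_map, q.chromosome, q.position_cM)
        effects[j, 0] += q.effect_trait1
        effects[j, 1] += q.effect_trait2

    liability = np.asarray(arch.baseline_liability, float)[None, :] + dosage @ effects

    n_loci, total_sd = arch.polygenic_background
    if kinship_like_background and n_loci > 0 and total_sd > 0:
        loci = rng.choice(genotypes.n_markers, size=min(n_loci, genotypes.n_markers),
                          replace=False)
        for t in range(2):
            w = rng.normal(size=len(loci))
            bg = dosage[:, loci] @ w
            sd = bg.std()
            if sd > 0:
                liability[:, t] += bg * (total_sd / sd)

    if arch.strain_noise_sd > 0:
        liability += rng.normal(0.0, arch.strain_noise_sd, size=(n, 2))

    penetrance = np.clip(_logistic(liability), 1e-6, 1.0 - 1e-6)

    counts = rng.binomial(arch.embryos_per_replicate,
                          penetrance[:, :, None],
                          size=(n, 2, arch.replicates))
    fractions = counts / arch.embryos_per_replicate
    values = fractions.mean(axis=2)

    rows = []
    for i, strain in enumerate(genotypes.strain_ids):
        for t, trait in enumerate(arch.trait_names):
            for r in range(arch.replicates):
                rows.append({"strain": strain, "trait": trait, "replicate": r + 1,
                             "n_scored": arch.embryos_per_replicate,
                             "n_with_gut": int(counts[i, t, r])})
    reps = pd.DataFrame(rows)
    wide = pd.DataFrame(values, index=genotypes.strain_ids,
                        columns=list(arch.trait_names))
    return PhenotypeTable(wide, reps)


# ---------------------------------------------------------------------------
# trait on a tree
# ---------------------------------------------------------------------------

def bm_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance of a tree: C[i, j] = shared root-to-MRCA
    path length, C[i, i] = root-to-tip depth."""
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    depth = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            if node.edge.length is None or node.edge.length < 0:
                raise DataError("tree must have nonnegative branch lengths")
            d += node.edge.length
            node = node.parent_node
        depth[leaf.taxon.label] = d
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    C = np.zeros((n, n))
    tax_objs = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(taxa):
        C[i, i] = depth[a]
        for j in range(i + 1, n):
            b = taxa[j]
            dist = pdm.patristic_distance(tax_objs[a], tax_objs[b])
            C[i, j] = C[j, i] = 0.5 * (depth[a] + depth[b] - dist)
    return taxa, C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel transformation: scale off-diagonal covariance by lambda."""
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def simulate_trait_on_tree(tree: dendropy.Tree, lambda_true: float, rate: float,
                           seed: int | None = 0) -> pd.Series:
    """Tip values from MVN(0, rate * C_lambda) for phylogenetic-signal tests."""
    if not 0.0 <= lambda_true <= 1.0:
        raise ConfigurationError(f"lambda must lie in [0, 1], got {lambda_true}")
    if rate <= 0:
        raise ConfigurationError("rate must be positive")
    rng = np.random.default_rng(seed)
    taxa, C = bm_covariance(tree)
    cov = rate * lambda_transform(C, lambda_true)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(taxa)))
    return pd.Series(L @ rng.normal(size=len(taxa)), index=taxa)
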