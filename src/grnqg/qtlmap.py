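"""Interval mapping for selfed recombinant inbred lines.

A two-state hidden Markov model (parental classes AA / BB) supplies genotype
probabilities along each chromosome: map distances convert to recombination
fractions with Haldane's inverse map r = (1 - exp(-2d)) / 2 and the selfed-
RIL map expansion r_RIL = 2r / (1 + 2r) (Haldane-Waddington), residual
heterozygote calls are treated as missing, and a symmetric genotyping-error
rate enters the emissions. Standard interval mapping then fits, at every
marker and pseudomarker, a two-component normal mixture with known mixing
proportions by EM (class means + common variance) and reports
LOD = log10 L1 / L0 against the single-normal null. Genome-wide significance
comes from phenotype permutations (max-LOD order statistic) and QTL regions
from 1.5-LOD support intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import MISSING, GenotypeMatrix, MarkerMap
from .errors import ConfigurationError, DataError

__all__ = [
    "CrossPopulation",
    "GenotypeProbabilities",
    "LodCurve",
    "QtlPeak",
    "map_to_recfrac",
    "ril_recfrac",
    "calc_genoprob",
    "scanone_em",
    "permutation_threshold",
    "lod_support_interval",
    "genotype_group_summary",
]

DEFAULT_STEP_CM = 1.0
DEFAULT_ERROR_RATE = 1e-4
DEFAULT_EM_TOL = 1e-6
DEFAULT_EM_MAX_ITER = 4000


def map_to_recfrac(d) -> np.ndarray | float:
    """Haldane inverse map: distance in cM to recombination fraction."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ConfigurationError("map distance must be >= 0 cM")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def ril_recfrac(r) -> np.ndarray | float:
    """Haldane-Waddington expansion for selfed RILs: r_RIL = 2r / (1 + 2r)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ConfigurationError("recombination fraction must lie in [0, 0.5]")
    out = 2.0 * r / (1.0 + 2.0 * r)
    return float(out) if out.ndim == 0 else out


@dataclass
class CrossPopulation:
    """A selfed-RIL cross: genotypes in parental codes (0 = A, 2 = B,
    1 = residual heterozygote) and a cM-resolved marker map."""

    genotypes: GenotypeMatrix
    marker_map: MarkerMap

    def __post_init__(self) -> None:
        if self.marker_map.marker_ids != self.genotypes.marker_ids:
            raise DataError("marker map does not match genotype matrix columns")
        if np.isnan(self.marker_map.frame["cM"].to_numpy(float)).any():
            raise DataError("cross map needs genetic (cM) positions")

    @property
    def n_rils(self) -> int:
        return self.genotypes.n_strains


@dataclass
class GenotypeProbabilities:
    """P(class | data) on the evaluation grid; class order (AA, BB)."""

    positions: pd.DataFrame  # chrom, cM, is_pseudomarker, marker (id or "")
    probs: np.ndarray  # (n_rils, n_positions, 2)
    strain_ids: list[str]


@dataclass
class LodCurve:
    frame: pd.DataFrame  # chrom, cM, lod, converged

    def chrom(self, chromosome: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chromosome]

    @property
    def max_lod(self) -> float:
        return float(self.frame["lod"].max())


@dataclass
class QtlPeak:
    chromosome: str
    peak_cM: float
    peak_lod: float
    interval_lo_cM: float
    interval_hi_cM: float
    threshold: float | None = None

    @property
    def has_peak(self) -> bool:
        return np.isfinite(self.peak_lod) and self.peak_lod > 0


# ---------------------------------------------------------------------------
# genotype probabilities (forward-backward)
# ---------------------------------------------------------------------------

def _grid_positions(marker_map: MarkerMap, chrom: str, step_cm: float):
    idx = marker_map.chrom_markers(chrom)
    cm = marker_map.frame["cM"].to_numpy(float)[idx]
    ids = [marker_map.marker_ids[i] for i in idx]
    if step_cm <= 0:
        return cm, ids, idx, np.zeros(len(cm), dtype=bool)
    grid = [cm[0]]
    grid_ids = [ids[0]]
    pseudo = [False]
    src = [idx[0]]
    for k in range(1, len(cm)):
        pos = grid[-1] + step_cm
        while pos < cm[k] - 1e-9:
            grid.append(pos)
            grid_ids.append("")
            pseudo.append(True)
            src.append(-1)
            pos += step_cm
        grid.append(cm[k])
        grid_ids.append(ids[k])
        pseudo.append(False)
        src.append(idx[k])
    return np.array(grid), grid_ids, np.array(src), np.array(pseudo)


def calc_genoprob(cross: CrossPopulation, step_cM: float = DEFAULT_STEP_CM,
                  error_rate: float = DEFAULT_ERROR_RATE) -> GenotypeProbabilities:
    """Forward-backward genotype probabilities for every RIL at markers and
    pseudomarkers spaced ``step_cM`` apart (``step_cM = 0``: markers only).

    Heterozygote observations are treated as missing (selfed-RIL two-class
    model); emissions allow a symmetric genotyping error."""
    if step_cM < 0:
        raise ConfigurationError("step_cM must be >= 0")
    if not 0.0 <= error_rate < 0.5:
        raise ConfigurationError("error_rate must lie in [0, 0.5)")
    mm = cross.marker_map
    G = cross.genotypes.values
    n = cross.n_rils
    pos_frames = []
    prob_blocks = []
    for chrom in mm.chromosomes():
        grid, grid_ids, src, pseudo = _grid_positions(mm, chrom, step_cM)
        P = len(grid)
        # emission matrix (n, P, 2); uniform for pseudomarkers/missing/het
        emit = np.ones((n, P, 2))
        for k in range(P):
            if src[k] < 0:
                continue
            g = G[:, src[k]]
            obs_a = g == 0
            obs_b = g == 2
            emit[obs_a, k, 0] = 1.0 - error_rate
            emit[obs_a, k, 1] = error_rate
            emit[obs_b, k, 0] = error_rate
            emit[obs_b, k, 1] = 1.0 - error_rate
        r = ril_recfrac(map_to_recfrac(np.diff(grid)))
        r = np.atleast_1d(r)
        # forward
        fwd = np.empty((n, P, 2))
        fwd[:, 0] = 0.5 * emit[:, 0]
        scale = np.empty((n, P))
        scale[:, 0] = fwd[:, 0].sum(axis=1)
        fwd[:, 0] /= scale[:, 0, None]
        for k in range(1, P):
            stay, move = 1.0 - r[k - 1], r[k - 1]
            pred = np.empty((n, 2))
            pred[:, 0] = fwd[:, k - 1, 0] * stay + fwd[:, k - 1, 1] * move
            pred[:, 1] = fwd[:, k - 1, 0] * move + fwd[:, k - 1, 1] * stay
            fwd[:, k] = pred * emit[:, k]
            scale[:, k] = fwd[:, k].sum(axis=1)
            fwd[:, k] /= scale[:, k, None]
        # backward
        bwd = np.ones((n, P, 2))
        for k in range(P - 2, -1, -1):
            stay, move = 1.0 - r[k], r[k]
            nxt = bwd[:, k + 1] * emit[:, k + 1]
            bwd[:, k, 0] = nxt[:, 0] * stay + nxt[:, 1] * move
            bwd[:, k, 1] = nxt[:, 0] * move + nxt[:, 1] * stay
            bwd[:, k] /= bwd[:, k].sum(axis=1, keepdims=True)
        post = fwd * bwd
        post /= post.sum(axis=2, keepdims=True)
        prob_blocks.append(post)
        pos_frames.append(pd.DataFrame({
            "chrom": chrom, "cM": grid, "is_pseudomarker": pseudo,
            "marker": grid_ids,
        }))
    positions = pd.concat(pos_frames, ignore_index=True)
    probs = np.concatenate(prob_blocks, axis=1)
    return GenotypeProbabilities(positions, probs, list(cross.genotypes.strain_ids))


# ---------------------------------------------------------------------------
# EM interval mapping
# ---------------------------------------------------------------------------

def _null_loglik(y: np.ndarray) -> float:
    n = y.size
    var0 = y.var()
    if var0 <= 0:
        return 0.0
    return float(-0.5 * n * (np.log(2 * np.pi * var0) + 1.0))


def _em_mixture(y: np.ndarray, prior: np.ndarray, tol: float, max_iter: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """EM for a known-mixing two-normal mixture at every position at once.

    ``prior`` has shape (n, P, 2); returns (loglik per position, converged
    flags). The common variance is shared by the two classes.
    """
    n, P, _ = prior.shape
    w = prior.copy()
    wsum = w.sum(axis=0)  # (P, 2)
    mu = np.einsum("i,ipk->pk", y, w) / np.maximum(wsum, 1e-300)
    resid2 = (y[:, None, None] - mu[None, :, :]) ** 2
    var = np.einsum("ipk,ipk->p", w, resid2) / n
    var = np.maximum(var, 1e-300)
    ll_old = np.full(P, -np.inf)
    converged = np.zeros(P, dtype=bool)
    ll = ll_old
    for _ in range(max_iter):
        # E step: weights and observed-data loglik under current params
        log_comp = (-0.5 * np.log(2 * np.pi * var)[None, :, None]
                    - resid2 / (2 * var[None, :, None]))
        with np.errstate(divide="ignore"):
            log_num = np.log(np.maximum(prior, 1e-300)) + log_comp
        mx = log_num.max(axis=2, keepdims=True)
        lse = mx[:, :, 0] + np.log(np.exp(log_num - mx).sum(axis=2))
        ll = lse.sum(axis=0)  # (P,)
        done = np.abs(ll - ll_old) < tol
        converged |= done
        if done.all():
            break
        ll_old = ll
        w = np.exp(log_num - lse[:, :, None])
        # M step
        wsum = w.sum(axis=0)
        mu = np.einsum("i,ipk->pk", y, w) / np.maximum(wsum, 1e-300)
        resid2 = (y[:, None, None] - mu[None, :, :]) ** 2
        var = np.einsum("ipk,ipk->p", w, resid2) / n
        var = np.maximum(var, 1e-300)
    return ll, converged


def scanone_em(cross: CrossPopulation, phenotype, step_cM: float = DEFAULT_STEP_CM,
               error_rate: float = DEFAULT_ERROR_RATE, tol: float = DEFAULT_EM_TOL,
               max_iter: int = DEFAULT_EM_MAX_ITER,
               genoprob: GenotypeProbabilities | None = None) -> LodCurve:
    """Standard interval mapping by EM; LOD against the single-normal null.

    ``phenotype`` is a vector aligned to the cross strains or a pandas Series
    indexed by strain id (NaN = unphenotyped; those RILs are dropped). A
    precomputed ``genoprob`` may be passed to amortise the HMM across
    permutations.
    """
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(cross.genotypes.strain_ids).to_numpy(float)
    else:
        y = np.asarray(phenotype, float).ravel()
        if y.size != cross.n_rils:
            raise DataError("phenotype length does not match cross strains")
    keep = ~np.isnan(y)
    if keep.sum() < 10:
        raise DataError("phenotype available for fewer than 10 RILs")
    gp = genoprob if genoprob is not None else calc_genoprob(cross, step_cM, error_rate)
    y_obs = y[keep]
    prior = gp.probs[keep]
    if np.ptp(y_obs) == 0:
        warnings.warn("constant phenotype: LOD curve is identically zero")
        lod = np.zeros(len(gp.positions))
        converged = np.ones(len(gp.positions), dtype=bool)
    else:
        ll1, converged = _em_mixture(y_obs, prior, tol, max_iter)
        ll0 = _null_loglik(y_obs)
        lod = (ll1 - ll0) / np.log(10.0)
        if np.any(lod < -1e-8):
            warnings.warn("negative LOD beyond tolerance; flooring at 0")
        lod = np.maximum(lod, 0.0)
        if not converged.all():
            warnings.warn(f"EM did not converge at {(~converged).sum()} positions; "
                          "last iterate reported")
    frame = gp.positions.copy()
    frame["lod"] = lod
    frame["converged"] = converged
    return LodCurve(frame)


def permutation_threshold(cross: CrossPopulation, phenotype,
                          n_permutations: int = 1000, alpha: float = 0.05,
                          seed: int | None = 0, step_cM: float = DEFAULT_STEP_CM,
                          error_rate: float = DEFAULT_ERROR_RATE,
                          return_maxima: bool = False):
    """Genome-wide max-LOD permutation threshold.

    The phenotype is permuted against the genotypes; the threshold is the
    ceil((1 - alpha) N)-th order statistic of the per-permutation genome-wide
    maximum LOD.
    """
    if n_permutations < 100:
        raise ConfigurationError("n_permutations must be >= 100")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(cross.genotypes.strain_ids).to_numpy(float)
    else:
        y = np.asarray(phenotype, float).ravel()
    keep = ~np.isnan(y)
    gp = calc_genoprob(cross, step_cM, error_rate)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_permutations)
    yp = y.copy()
    obs_idx = np.flatnonzero(keep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_permutations):
            yp[obs_idx] = y[obs_idx][rng.permutation(obs_idx.size)]
            curve = scanone_em(cross, yp, step_cM, error_rate, genoprob=gp)
            maxima[b] = curve.max_lod
    k = int(np.ceil((1.0 - alpha) * n_permutations))
    threshold = float(np.sort(maxima)[min(k, n_permutations) - 1])
    if return_maxima:
        return threshold, maxima
    return threshold


def lod_support_interval(curve: LodCurve, chromosome: str, drop: float = 1.5,
                         threshold: float | None = None) -> QtlPeak:
    """1.5-LOD (by default) support interval around the chromosome peak.

    Interval endpoints are the outermost positions flanking the peak where
    LOD >= peak - drop, linearly interpolated between grid points and clipped
    to the chromosome ends. An all-zero curve yields a no-peak result.
    """
    sub = curve.chrom(chromosome)
    if sub.empty:
        raise DataError(f"curve does not cover chromosome {chromosome!r}")
    cm = sub["cM"].to_numpy(float)
    lod = sub["lod"].to_numpy(float)
    if np.all(lod <= 1e-12):
        return QtlPeak(chromosome, np.nan, 0.0, np.nan, np.nan, threshold)
    k = int(np.argmax(lod))
    cut = lod[k] - drop
    lo = cm[0]
    for i in range(k, 0, -1):
        if lod[i - 1] < cut:
            frac = (lod[i] - cut) / (lod[i] - lod[i - 1])
            lo = cm[i] - frac * (cm[i] - cm[i - 1])
            break
    hi = cm[-1]
    for i in range(k, len(cm) - 1):
        if lod[i + 1] < cut:
            frac = (lod[i] - cut) / (lod[i] - lod[i + 1])
            hi = cm[i] + frac * (cm[i + 1] - cm[i])
            break
    return QtlPeak(chromosome, float(cm[k]), float(lod[k]), float(lo), float(hi),
                   threshold)


def genotype_group_summary(phenotype, classes) -> pd.DataFrame:
    """Per-genotype-class summary: n, mean, t-based 95% CI of the mean,
    median and quartiles (linear-interpolation quantiles).

    Classes with fewer than two observations are flagged (``ci_defined`` is
    False and the CI columns are NaN).
    """
    y = np.asarray(phenotype, float).ravel()
    cls = np.asarray(classes).ravel()
    if y.size != cls.size:
        raise DataError("phenotype and class vectors differ in length")
    keep = ~pd.isna(y) & ~pd.isna(cls)
    y, cls = y[keep], cls[keep]
    rows = []
    for c in pd.unique(cls):
        v = np.sort(y[cls == c])
        row = {"class": c, "n": v.size, "mean": v.mean() if v.size else np.nan,
               "ci_lo": np.nan, "ci_hi": np.nan,
               "median": float(np.median(v)) if v.size else np.nan,
               "q1": float(np.quantile(v, 0.25)) if v.size else np.nan,
               "q3": float(np.quantile(v, 0.75)) if v.size else np.nan,
               "ci_defined": v.size >= 2}
        if v.size >= 2:
            sem = v.std(ddof=1) / np.sqrt(v.size)
            tcrit = stats.t.ppf(0.975, v.size - 1)
            row["ci_lo"] = row["mean"] - tcrit * sem
            row["ci_hi"] = row["mean"] + tcrit * sem
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
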