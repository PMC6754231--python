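"""Mixed-model association for inbred panels with permutation-based FDR.

The model is the single-random-effect linear mixed model

    y = X beta + g + e,   Var(g) = sigma_g^2 K,   Var(e) = sigma_e^2 I,

with K an identity-by-state kinship matrix. Writing delta = sigma_e^2 /
sigma_g^2 gives Var(y) = sigma_g^2 (K + delta I); the restricted likelihood
is profiled over delta through the eigendecomposition of S K S, where S is
the projection orthogonal to the column space of X. The scan refits the
variance components exactly for every tested marker (the marker enters the
fixed effects), and two-sided p-values come from the t distribution with
n - rank([X, marker]) degrees of freedom.

Genome-wide significance is assessed by permuting the phenotype against the
fixed genotypes and kinship: the ratio estimator

    FDR(t) = mean permuted #[p <= t] / max(1, observed #[p <= t])

gives per-marker FDR estimates (monotonised step-up), and the per-permutation
minimum p supplies a family-wise max-statistic threshold for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import MISSING, GenotypeMatrix
from .errors import ConfigurationError, DataError

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "AssociationScan",
    "FdrResult",
    "ibs_kinship",
    "emma_reml_fit",
    "emma_scan",
    "permutation_fdr",
]

_LOG10_DELTA_RANGE = (-5.0, 5.0)
_N_GRID_INTERVALS = 100


@dataclass
class KinshipMatrix:
    strain_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if self.values.shape != (n, n):
            raise DataError("kinship matrix shape inconsistent with strain ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("kinship matrix must be symmetric")

    def subset(self, idx: np.ndarray) -> "KinshipMatrix":
        idx = np.asarray(idx)
        return KinshipMatrix([self.strain_ids[i] for i in idx],
                             self.values[np.ix_(idx, idx)])


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    beta: np.ndarray | None = None
    at_boundary: bool = False


@dataclass
class AssociationScan:
    """Per-marker mixed-model test results (index = marker id)."""

    table: pd.DataFrame  # chrom, bp, maf, tested, beta, se, t, p, minus_log10_p,
    #                      median_ref, median_alt
    n_strains: int

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["tested"]]


@dataclass
class FdrResult:
    marker_fdr: pd.Series  # per tested marker, clipped to [0, 1]
    thresholds: pd.DataFrame  # p_cutoff, fdr  (per observed p treated as cutoff)
    maxstat_p_threshold: float  # family-wise alpha-quantile of per-perm min p
    n_permutations: int
    alpha: float


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def ibs_kinship(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: K[i, j] = mean over markers non-missing in
    both strains of 1 - |g_i - g_j| / 2."""
    if genotypes.n_strains < 2 or genotypes.n_markers < 1:
        raise DataError("kinship needs >= 2 strains and >= 1 marker")
    G = genotypes.values
    obs = genotypes.observed().astype(np.float64)
    # |a-b| over codes {0,1,2} decomposes through per-code indicators
    ind = [((G == c) & (G != MISSING)).astype(np.float64) for c in (0, 1, 2)]
    absdiff = np.zeros((genotypes.n_strains, genotypes.n_strains))
    for a in range(3):
        for b in range(3):
            if a != b:
                absdiff += abs(a - b) * (ind[a] @ ind[b].T)
    shared = obs @ obs.T
    if np.any(shared == 0):
        i, j = np.argwhere(shared == 0)[0]
        raise DataError(
            f"strains {genotypes.strain_ids[i]!r} and {genotypes.strain_ids[j]!r} "
            "share no non-missing markers"
        )
    K = 1.0 - absdiff / (2.0 * shared)
    K = 0.5 * (K + K.T)
    return KinshipMatrix(list(genotypes.strain_ids), K)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _projected_spectrum(X: np.ndarray, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of S K S on the complement of col(X).

    Returns (lambdas, U) with U of shape (n, q), q = n - rank(X); the q
    retained eigenvectors are those orthogonal to col(X).
    """
    n = X.shape[0]
    Q, R = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())))
    if rank < X.shape[1]:
        raise DataError("covariate matrix is rank deficient")
    S = np.eye(n) - Q[:, :rank] @ Q[:, :rank].T
    M = S @ K @ S
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    q = n - rank
    lambdas = w[-q:][::-1].copy()
    U = V[:, -q:][:, ::-1].copy()
    return np.maximum(lambdas, 0.0), U


def _reml_loglik(delta: np.ndarray | float, lambdas: np.ndarray,
                 eta2: np.ndarray) -> np.ndarray | float:
    """Restricted log-likelihood profile in delta (constants included)."""
    delta = np.asarray(delta, dtype=float)
    q = lambdas.size
    denom = lambdas[..., None] + delta if delta.ndim else lambdas + delta
    s1 = (eta2[..., None] / denom).sum(axis=0) if delta.ndim else (eta2 / denom).sum()
    s2 = np.log(denom).sum(axis=0) if delta.ndim else np.log(denom).sum()
    return 0.5 * (q * np.log(q / (2 * np.pi)) - q - q * np.log(s1) - s2)


def _reml_dloglik(delta: float, lambdas: np.ndarray, eta2: np.ndarray) -> float:
    d = lambdas + delta
    s1 = (eta2 / d).sum()
    s2 = (eta2 / d**2).sum()
    s3 = (1.0 / d).sum()
    return 0.5 * (lambdas.size * s2 / s1 - s3)


def _optimise_delta(lambdas: np.ndarray, eta2: np.ndarray) -> tuple[float, float, bool]:
    """Global REML optimum of delta via grid + derivative sign-change roots.

    Returns (delta_hat, loglik, at_boundary).
    """
    lo, hi = _LOG10_DELTA_RANGE
    grid = 10.0 ** np.linspace(lo, hi, _N_GRID_INTERVALS + 1)
    # vectorised derivative over the grid
    denom = lambdas[:, None] + grid[None, :]
    s1 = (eta2[:, None] / denom).sum(axis=0)
    s2 = (eta2[:, None] / denom**2).sum(axis=0)
    s3 = (1.0 / denom).sum(axis=0)
    dvals = 0.5 * (lambdas.size * s2 / s1 - s3)
    candidates = [grid[0], grid[-1]]
    for i in range(len(grid) - 1):
        if np.sign(dvals[i]) != np.sign(dvals[i + 1]) and dvals[i] != 0:
            try:
                root = optimize.brentq(_reml_dloglik, grid[i], grid[i + 1],
                                       args=(lambdas, eta2), xtol=1e-12, rtol=1e-12)
                candidates.append(root)
            except ValueError:
                pass
    lls = [float(_reml_loglik(d, lambdas, eta2)) for d in candidates]
    best = int(np.argmax(lls))
    at_boundary = best in (0, 1)
    return float(candidates[best]), float(lls[best]), at_boundary


def _check_psd(K: np.ndarray, tol: float = 1e-6) -> None:
    wmin = np.linalg.eigvalsh(0.5 * (K + K.T)).min()
    if wmin < -tol:
        raise DataError(f"kinship matrix is not PSD (min eigenvalue {wmin:.3g})")


def emma_reml_fit(y: np.ndarray, X: np.ndarray, K: KinshipMatrix | np.ndarray
                  ) -> VarianceComponents:
    """REML fit of the variance ratio delta = sigma_e^2 / sigma_g^2.

    The restricted likelihood is profiled through the spectrum of S K S, a
    100-interval grid on log10 delta in [-5, 5] locates sign changes of its
    derivative, and each bracket is refined to a root; the global optimum
    (including the boundary) is returned together with the GLS fixed
    effects.
    """
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    n = y.size
    if Kv.shape != (n, n):
        raise DataError("kinship dimensions do not match phenotype")
    if n < X.shape[1] + 2:
        raise DataError("too few observations for the fixed effects")
    _check_psd(Kv)
    lambdas, U = _projected_spectrum(X, Kv)
    eta2 = (U.T @ y) ** 2
    delta, ll, at_boundary = _optimise_delta(lambdas, eta2)
    q = lambdas.size
    sigma_g2 = float((eta2 / (lambdas + delta)).sum() / q)
    sigma_e2 = float(delta * sigma_g2)
    beta, _, _, _ = _gls(y, X, Kv, delta)
    return VarianceComponents(sigma_g2, sigma_e2, float(delta), ll, beta=beta,
                              at_boundary=at_boundary)


def _gls(y: np.ndarray, X: np.ndarray, K: np.ndarray, delta: float
         ) -> tuple[np.ndarray, np.ndarray, float, int]:
    """GLS under Var(y) = sigma_g^2 (K + delta I).

    Returns (beta_hat, cov_unscaled, sigma_g2_reml, df) where the covariance
    of beta_hat is sigma_g2 * cov_unscaled and df = n - p.
    """
    n, p = X.shape
    H = K + delta * np.eye(n)
    Hinv_X = np.linalg.solve(H, X)
    Hinv_y = np.linalg.solve(H, y)
    XtHiX = X.T @ Hinv_X
    beta = np.linalg.solve(XtHiX, X.T @ Hinv_y)
    resid = y - X @ beta
    sigma_g2 = float(resid @ np.linalg.solve(H, resid) / (n - p))
    return beta, np.linalg.inv(XtHiX), sigma_g2, n - p


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

@dataclass
class _MarkerWork:
    """Per-marker precomputation reused across permutations."""

    j: int
    idx: np.ndarray  # complete-case strain indices (into the aligned arrays)
    X: np.ndarray  # covariates + marker dosage
    lambdas: np.ndarray
    U: np.ndarray
    K_sub: np.ndarray
    df: int


def _prepare_scan(y, genotypes: GenotypeMatrix, K: KinshipMatrix,
                  covariates: np.ndarray | None, min_maf: float):
    yv = np.asarray(y, float).ravel()
    n = genotypes.n_strains
    if yv.size != n:
        raise DataError("phenotype length does not match genotype strains")
    if K.strain_ids != genotypes.strain_ids:
        raise DataError("kinship strains do not match genotype strains")
    pheno_ok = ~np.isnan(yv)
    if pheno_ok.sum() < n / 2:
        raise DataError("phenotype missing for more than half the strains")
    base_idx = np.flatnonzero(pheno_ok)
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        if not np.allclose(C[:, 0], 1.0):
            C = np.column_stack([np.ones(n), C])
    maf = genotypes.maf()
    works: list[_MarkerWork | None] = []
    for j in range(genotypes.n_markers):
        g = genotypes.values[:, j]
        idx = base_idx[g[base_idx] != MISSING]
        if maf[j] < min_maf or idx.size < C.shape[1] + 3:
            works.append(None)
            continue
        gj = g[idx].astype(float)
        if np.ptp(gj) == 0:
            works.append(None)
            continue
        X = np.column_stack([C[idx], gj])
        K_sub = K.values[np.ix_(idx, idx)]
        try:
            lambdas, U = _projected_spectrum(X, K_sub)
        except DataError:
            works.append(None)
            continue
        works.append(_MarkerWork(j, idx, X, lambdas, U, K_sub, idx.size - X.shape[1]))
    return yv, works, maf


def _marker_pvalue(work: _MarkerWork, yv: np.ndarray) -> tuple[float, float, float, float]:
    """Exact per-marker refit; returns (beta, se, t, p)."""
    ysub = yv[work.idx]
    eta2 = (work.U.T @ ysub) ** 2
    delta, _, _ = _optimise_delta(work.lambdas, eta2)
    beta, cov_unscaled, sigma_g2, df = _gls(ysub, work.X, work.K_sub, delta)
    se = float(np.sqrt(sigma_g2 * cov_unscaled[-1, -1]))
    t = float(beta[-1] / se) if se > 0 else 0.0
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(beta[-1]), se, t, max(p, np.finfo(float).tiny)


def _marker_pvalues_batch(work: _MarkerWork, Y: np.ndarray) -> np.ndarray:
    """Exact per-marker refit for many phenotype vectors at once.

    ``Y`` is (n_aligned, P); returns the length-P vector of two-sided
    p-values. The REML optimum in delta is located per column with the same
    grid + derivative-root scheme as the scalar path (roots refined by
    bisection), so permuted and observed statistics are exchangeable.
    """
    Ysub = Y[work.idx]  # (n, P)
    n, P = Ysub.shape
    lambdas = work.lambdas
    q = lambdas.size
    Eta2 = (work.U.T @ Ysub) ** 2  # (q, P)
    lo, hi = _LOG10_DELTA_RANGE
    grid = 10.0 ** np.linspace(lo, hi, _N_GRID_INTERVALS + 1)
    A = 1.0 / (lambdas[:, None] + grid[None, :])  # (q, G)
    s3 = A.sum(axis=0)  # (G,)
    sumlog = -np.log(A).sum(axis=0)  # (G,)
    S1 = A.T @ Eta2  # (G, P)
    S2 = (A**2).T @ Eta2
    dll = 0.5 * (q * S2 / S1 - s3[:, None])  # (G, P)
    ll = 0.5 * (q * np.log(q / (2 * np.pi)) - q - q * np.log(S1)
                - sumlog[:, None])  # (G, P)

    def dll_at(delta: np.ndarray) -> np.ndarray:
        denom = lambdas[:, None] + delta[None, :]
        s1 = (Eta2 / denom).sum(axis=0)
        s2 = (Eta2 / denom**2).sum(axis=0)
        s3v = (1.0 / denom).sum(axis=0)
        return 0.5 * (q * s2 / s1 - s3v)

    def ll_at(delta: np.ndarray) -> np.ndarray:
        denom = lambdas[:, None] + delta[None, :]
        s1 = (Eta2 / denom).sum(axis=0)
        return 0.5 * (q * np.log(q / (2 * np.pi)) - q - q * np.log(s1)
                      - np.log(denom).sum(axis=0))

    # candidates: both boundaries plus bisected roots of every sign-change run
    best_delta = np.where(ll[0] >= ll[-1], grid[0], grid[-1])
    best_ll = np.maximum(ll[0], ll[-1])
    sign_change = (np.sign(dll[:-1]) != np.sign(dll[1:])) & (dll[:-1] != 0)
    max_runs = int(sign_change.sum(axis=0).max()) if P else 0
    order = np.argsort(~sign_change, axis=0, kind="stable")  # True rows first
    for r in range(max_runs):
        cell = order[r]  # grid cell index per column
        active = sign_change[cell, np.arange(P)]
        lo_d = grid[cell]
        hi_d = grid[np.minimum(cell + 1, len(grid) - 1)]
        for _ in range(60):
            mid = 0.5 * (lo_d + hi_d)
            dm = dll_at(mid)
            go_right = np.sign(dm) == np.sign(dll[cell, np.arange(P)])
            lo_d = np.where(go_right, mid, lo_d)
            hi_d = np.where(go_right, hi_d, mid)
        root = 0.5 * (lo_d + hi_d)
        ll_root = ll_at(root)
        better = active & (ll_root > best_ll)
        best_delta = np.where(better, root, best_delta)
        best_ll = np.where(better, ll_root, best_ll)

    # GLS t-test via the spectral form of H = K + delta I
    if not hasattr(work, "_eig"):
        xi, Q = np.linalg.eigh(0.5 * (work.K_sub + work.K_sub.T))
        work._eig = (np.maximum(xi, 0.0), Q)  # type: ignore[attr-defined]
    xi, Q = work._eig  # type: ignore[attr-defined]
    Xt = Q.T @ work.X  # (n, p)
    Yt = Q.T @ Ysub  # (n, P)
    W = 1.0 / (xi[:, None] + best_delta[None, :])  # (n, P)
    p_dim = Xt.shape[1]
    a = np.einsum("np,nc,nd->pcd", W, Xt, Xt)
    b = np.einsum("np,nc,np->pc", W, Xt, Yt)
    beta = np.linalg.solve(a, b[..., None])[..., 0]  # (P, p_dim)
    yWy = (W * Yt**2).sum(axis=0)
    rss = yWy - np.einsum("pc,pc->p", beta, b)
    df = n - p_dim
    sigma_g2 = rss / df
    a_inv_last = np.linalg.inv(a)[:, -1, -1]
    se = np.sqrt(np.maximum(sigma_g2 * a_inv_last, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, -1] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.maximum(p, np.finfo(float).tiny)


def emma_scan(y, genotypes: GenotypeMatrix, K: KinshipMatrix,
              covariates: np.ndarray | None = None, min_maf: float = 0.05,
              marker_map=None) -> AssociationScan:
    """Exact mixed-model scan: variance components refit per marker.

    Markers failing the MAF filter, monomorphic after missingness, or with
    too few complete cases are flagged untested. ``y`` may contain NaN for
    unphenotyped strains (complete-case analysis per marker).
    """
    yv, works, maf = _prepare_scan(y, genotypes, K, covariates, min_maf)
    rows = []
    for j, mid in enumerate(genotypes.marker_ids):
        work = works[j]
        row = {"marker": mid, "maf": maf[j], "tested": work is not None,
               "beta": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
               "minus_log10_p": np.nan, "median_ref": np.nan, "median_alt": np.nan}
        if work is not None:
            b, se, t, p = _marker_pvalue(work, yv)
            g = genotypes.values[work.idx, j]
            ysub = yv[work.idx]
            ref = ysub[g == 0]
            alt = ysub[g == 2]
            row.update(beta=b, se=se, t=t, p=p, minus_log10_p=-np.log10(p),
                       median_ref=float(np.median(ref)) if ref.size else np.nan,
                       median_alt=float(np.median(alt)) if alt.size else np.nan)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("marker")
    if marker_map is not None:
        table.insert(0, "chrom", marker_map.frame["chrom"].reindex(table.index))
        table.insert(1, "bp", marker_map.frame["bp"].reindex(table.index))
    scan = AssociationScan(table, n_strains=genotypes.n_strains)
    scan._works = works  # reused by permutation_fdr  # type: ignore[attr-defined]
    scan._y = yv  # type: ignore[attr-defined]
    return scan


def permutation_fdr(scan: AssociationScan, y, genotypes: GenotypeMatrix,
                    K: KinshipMatrix, n_permutations: int = 1000,
                    seed: int | None = 0, alpha: float = 0.05,
                    covariates: np.ndarray | None = None,
                    min_maf: float = 0.05) -> FdrResult:
    """Permutation FDR for a mixed-model scan.

    The phenotype vector is permuted across strains (kinship and genotypes
    fixed) and the full exact scan recomputed for each permutation. The
    ratio estimator FDR(t) = mean permuted #[p <= t] / max(1, #[p_obs <= t])
    is evaluated at each observed p, monotonised step-up and clipped to
    [0, 1]; the alpha-quantile of per-permutation minimum p is reported as a
    family-wise threshold.
    """
    if n_permutations < 100:
        raise ConfigurationError("n_permutations must be >= 100")
    works = getattr(scan, "_works", None)
    yv = getattr(scan, "_y", None)
    if works is None or yv is None:
        scan = emma_scan(y, genotypes, K, covariates, min_maf)
        works = scan._works  # type: ignore[attr-defined]
        yv = scan._y  # type: ignore[attr-defined]
    obs_p = scan.tested["p"].to_numpy()
    if obs_p.size == 0:
        raise DataError("no tested markers to assess")
    live = [w for w in works if w is not None]
    rng = np.random.default_rng(seed)
    obs_idx = np.flatnonzero(~np.isnan(yv))
    Y = np.tile(yv[:, None], (1, n_permutations))
    for b in range(n_permutations):
        Y[obs_idx, b] = yv[obs_idx][rng.permutation(obs_idx.size)]
    perm_p = np.empty((n_permutations, len(live)))
    for k, w in enumerate(live):
        perm_p[:, k] = _marker_pvalues_batch(w, Y)

    order = np.argsort(obs_p)
    sorted_p = obs_p[order]
    perm_flat = np.sort(perm_p.ravel())
    # mean permuted count of p <= t, for t at each observed p
    cum_perm = np.searchsorted(perm_flat, sorted_p, side="right") / n_permutations
    obs_count = np.arange(1, sorted_p.size + 1)
    fdr_sorted = cum_perm / np.maximum(1, obs_count)
    # step-up monotonisation (nondecreasing in the cutoff)
    fdr_sorted = np.minimum.accumulate(fdr_sorted[::-1])[::-1]
    fdr_sorted = np.clip(fdr_sorted, 0.0, 1.0)
    marker_ids = scan.tested.index.to_numpy()[order]
    marker_fdr = pd.Series(fdr_sorted, index=marker_ids).reindex(scan.tested.index)
    thresholds = pd.DataFrame({"p_cutoff": sorted_p, "fdr": fdr_sorted})
    min_p = perm_p.min(axis=1)
    k_stat = int(np.ceil(alpha * n_permutations))
    maxstat = float(np.sort(min_p)[max(k_stat - 1, 0)])
    return FdrResult(marker_fdr, thresholds, maxstat, n_permutations, alpha)
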