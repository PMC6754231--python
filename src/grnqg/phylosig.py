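"""SNP distances, neighbor-joining trees and Pagel's lambda.

The strain tree is built from the allele-sharing Hamming proportion (the
fraction of markers, non-missing in both strains, with differing genotype
codes) by Saitou-Nei neighbor joining with the standard Q-criterion;
negative branch lengths are clamped to zero with the deficit moved to the
sister branch, and ties break deterministically by taxon-name order.

Phylogenetic signal in a continuous trait is measured by Pagel's lambda:
the trait is modelled as multivariate normal with covariance
sigma^2 C_lambda, where C is the Brownian-motion covariance of the tree and
C_lambda scales its off-diagonal entries by lambda in [0, 1]. lambda, the
rate and the root mean are fitted jointly by maximum likelihood and the
significance of signal comes from the likelihood-ratio statistic
2 (lnL(lambda_hat) - lnL(0)) referred to chi-square with one degree of
freedom — a boundary case for which this reference distribution is the
conventional, slightly conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataio import GenotypeMatrix
from .errors import DataError
from .simdata import bm_covariance, lambda_transform

__all__ = [
    "DistanceMatrix",
    "LambdaFit",
    "snp_distance",
    "neighbor_joining",
    "pagel_lambda",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataError("distance matrix shape inconsistent with ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-10):
            raise DataError("distance matrix must have a zero diagonal")
        if np.any(self.values < -1e-12):
            raise DataError("distances must be >= 0")


@dataclass
class LambdaFit:
    lambda_hat: float
    rate: float  # sigma^2
    root_mean: float
    loglik: float  # at lambda_hat
    loglik_zero: float  # at lambda = 0
    lrt: float
    p_value: float


def snp_distance(genotypes: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Hamming proportion over markers non-missing in both strains."""
    if genotypes.n_strains < 3:
        raise DataError("need >= 3 strains for a distance matrix")
    G = genotypes.values
    obs = genotypes.observed().astype(float)
    same = np.zeros((genotypes.n_strains,) * 2)
    for c in (0, 1, 2):
        ind = (G == c).astype(float)
        same += ind @ ind.T
    shared = obs @ obs.T
    if np.any(shared == 0):
        i, j = np.argwhere(shared == 0)[0]
        raise DataError(
            f"strains {genotypes.strain_ids[i]!r} and {genotypes.strain_ids[j]!r} "
            "share no non-missing markers"
        )
    d = 1.0 - same / shared
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(genotypes.strain_ids), np.maximum(d, 0.0))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei agglomeration with the Q-criterion.

    Deterministic: ties in Q break by the lexicographically smallest
    (name_i, name_j) pair, where an internal node is named by its smallest
    descendant tip. Negative branch lengths are clamped to zero and the
    deficit moved to the sister branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise DataError("neighbor joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    nodes = []
    for label in dm.ids:
        nd = dendropy.Node()
        nd.taxon = taxa.get_taxon(label)
        nodes.append(nd)
    names = list(dm.ids)  # sort key per active node (smallest descendant tip)
    D = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((names[active[a]], names[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (totals[a] - totals[b]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = dendropy.Node()
        child_i, child_j = nodes[i], nodes[j]
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = li
        child_j.edge.length = lj
        # distances from the new node to the remaining taxa
        newd = np.zeros(D.shape[0] + 1)
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            newd[k] = 0.5 * (sub[a, c] + sub[b, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newd) - 1] = newd[:-1]
        D[: len(newd) - 1, -1] = newd[:-1]
        nodes.append(parent)
        names.append(min(names[i], names[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final trifurcation: three-point formulas give the terminal lengths
    i, j, k = active
    root = dendropy.Node()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def root_at_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Pseudo-root the tree at a named tip (display convention; lambda is
    unaffected by the choice)."""
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            node = leaf
            break
    if node is None:
        raise DataError(f"outgroup {outgroup!r} is not a tip of the tree")
    tree.to_outgroup_position(node, update_bipartitions=False)
    return tree


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

def _profile_loglik(lam: float, C: np.ndarray, y: np.ndarray
                    ) -> tuple[float, float, float]:
    """ML profile at fixed lambda: optimal (rate, mean) in closed form."""
    n = y.size
    Cl = lambda_transform(C, lam)
    try:
        L = np.linalg.cholesky(Cl)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ones = np.ones(n)
    a = np.linalg.solve(L, y)
    b = np.linalg.solve(L, ones)
    mu = float(b @ a / (b @ b))
    resid = a - mu * b
    sigma2 = float(resid @ resid / n)
    if sigma2 <= 0:
        return -np.inf, mu, sigma2
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(ll), mu, sigma2


def pagel_lambda(tree: dendropy.Tree, tip_values, lambda_max: float = 1.0
                 ) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda with a chi-square(1) LRT against
    lambda = 0 (phylogenetic independence).

    ``tip_values`` is a pandas Series (or mapping) keyed by tip label; labels
    must match the tree's tips exactly.
    """
    taxa, C = bm_covariance(tree)
    s = pd.Series(tip_values)
    if set(s.index) != set(taxa):
        raise DataError("tip value labels do not match the tree's tips")
    y = s.reindex(taxa).to_numpy(float)
    if y.size < 4:
        raise DataError("need >= 4 tips for a lambda fit")
    if np.ptp(y) == 0:
        raise DataError("zero-variance trait: lambda is undefined")

    grid = np.linspace(0.0, lambda_max, 101)
    lls = np.array([_profile_loglik(l, C, y)[0] for l in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda l: -_profile_loglik(l, C, y)[0],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    lam_hat = float(res.x) if -res.fun >= lls[k] else float(grid[k])
    ll_hat, mu_hat, sigma2_hat = _profile_loglik(lam_hat, C, y)
    ll0 = _profile_loglik(0.0, C, y)[0]
    if ll_hat < ll0:  # the optimum is at the lambda = 0 boundary
        lam_hat, ll_hat, mu_hat, sigma2_hat = 0.0, ll0, *_profile_loglik(0.0, C, y)[1:]
    lrt = max(2.0 * (ll_hat - ll0), 0.0)
    p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return LambdaFit(lam_hat, sigma2_hat, mu_hat, ll_hat, ll0, lrt, p)
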