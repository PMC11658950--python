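"""Pagel's λ phylogenetic signal for single traits over a language phylogeny.

Under Brownian motion a trait's covariance between two tips is
proportional to their shared root-to-ancestor path length. Pagel's λ
multiplies the off-diagonal entries of that covariance by a factor in
[0, 1]: λ = 1 is the full Brownian expectation (strong vertical signal),
λ = 0 makes tips independent (no signal). λ is estimated by maximising
the Gaussian (GLS) likelihood with the mean and rate profiled out, and a
likelihood-ratio test against λ = 0 with one degree of freedom gives the
p-value. Binary traits are analysed on the 0/1 scale with the same
continuous model.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import dendropy
import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from ._rand import rng_from_seed
from .io import read_newick

_BL_FLOOR = 1e-8


@dataclasses.dataclass
class PhyloSignalResult:
    lambda_hat: float
    loglik_at_hat: float
    loglik_at_zero: float
    p_value: float
    trait_name: str
    n_tips: int

    @property
    def statistic(self) -> float:
        return 2.0 * (self.loglik_at_hat - self.loglik_at_zero)


def phylo_covariance(tree: dendropy.Tree, tip_labels: list[str]) -> np.ndarray:
    """Shared-path-length (Brownian) covariance matrix for the given tips."""
    depth: dict = {}
    for node in tree.preorder_node_iter():
        bl = node.edge.length
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + max(
                bl if bl is not None else 0.0, _BL_FLOOR
            )
    tip_of = {l.taxon.label: l for l in tree.leaf_node_iter()}
    pdm = tree.phylogenetic_distance_matrix()
    n = len(tip_labels)
    C = np.zeros((n, n))
    for i, a in enumerate(tip_labels):
        C[i, i] = depth[tip_of[a]]
        for j in range(i + 1, n):
            b = tip_labels[j]
            patristic = pdm.patristic_distance(tip_of[a].taxon, tip_of[b].taxon)
            C[i, j] = C[j, i] = max(
                (depth[tip_of[a]] + depth[tip_of[b]] - patristic) / 2.0, 0.0
            )
    return C


def _profile_loglik(C: np.ndarray, y: np.ndarray, lam: float) -> float:
    """GLS log-likelihood at λ with the ancestral mean and Brownian rate
    profiled out analytically."""
    n = len(y)
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = (one @ Vi @ y) / (one @ Vi @ one)
    r = y - mu
    s2 = (r @ Vi @ r) / n
    if s2 <= 0:
        s2 = 1e-300
    return float(-0.5 * (n * (np.log(2 * np.pi * s2) + 1.0) + logdet))


def pagel_lambda(
    tree,
    trait: Mapping[str, float],
    bounds: tuple[float, float] = (0.0, 1.0),
    trait_name: str = "",
) -> PhyloSignalResult:
    """Estimate λ for one trait and test it against λ = 0.

    ``tree`` is a dendropy Tree, Newick string or path; ``trait`` maps tip
    labels to numeric values (binary traits as 0/1). Tips missing from
    either side are dropped with a warning; at least 10 shared tips are
    required. A star tree (no shared internal branch lengths) leaves λ
    unidentifiable and raises.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    tree_tips = {l.taxon.label for l in tree.leaf_node_iter()}
    common = sorted(set(trait) & tree_tips)
    dropped = (set(trait) | tree_tips) - set(common)
    if dropped and len(dropped) != 0 and (set(trait) - tree_tips):
        warnings.warn(
            f"{len(set(trait) - tree_tips)} trait tip(s) not in the tree were dropped",
            stacklevel=2,
        )
    if len(common) < 10:
        raise ValueError("need trait values on at least 10 tips of the tree")
    y = np.array([float(trait[t]) for t in common])
    C = phylo_covariance(tree, common)
    off = C[~np.eye(len(C), dtype=bool)]
    if np.max(np.abs(off)) < 1e-12:
        raise ValueError("star tree: tips share no path, λ is unidentifiable")

    lo, hi = bounds
    res = minimize_scalar(
        lambda lam: -_profile_loglik(C, y, lam), bounds=(lo, hi), method="bounded"
    )
    candidates = [(float(res.x), -float(res.fun))]
    for lam in (lo, hi):
        candidates.append((lam, _profile_loglik(C, y, lam)))
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll0 = _profile_loglik(C, y, 0.0)
    ll_hat = max(ll_hat, ll0)
    stat = 2.0 * (ll_hat - ll0)
    p = float(stats.chi2.sf(stat, df=1))
    return PhyloSignalResult(
        lambda_hat=lam_hat,
        loglik_at_hat=ll_hat,
        loglik_at_zero=ll0,
        p_value=p,
        trait_name=trait_name,
        n_tips=len(common),
    )


def simulate_brownian_trait(
    tree, sigma: float = 1.0, lam: float = 1.0, seed: int = 0
) -> dict[str, float]:
    """Draw one trait from the λ-scaled Brownian model on a tree (for
    power checks and calibration)."""
    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
    C = phylo_covariance(tree, tips)
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    rng = rng_from_seed(seed)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(tips)))
    y = sigma * (L @ rng.standard_normal(len(tips)))
    return dict(zip(tips, y))
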