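"""Cultural distance networks and tree-likeness statistics.

Societies are compared by the Euclidean distance between their archetype
membership rows. From the pairwise distance matrix this module builds a
Neighbor-Net split network (an agglomerative circular ordering of the
taxa plus non-negative least-squares split weights) and quantifies
tree-likeness with δ-scores and Q-residuals: for every quartet the three
pairwise-distance sums are ordered m1 >= m2 >= m3 and the quartet scores

    δ = (m1 - m2) / (m1 - m3)        (0 when m1 = m3)
    Q = (m1 - m2)^2                  (on distances scaled to mean 1)

are averaged over all quartets (and per taxon). On an additive tree
metric every quartet satisfies the four-point condition (m1 = m2), both
statistics are zero and the network collapses to the neighbour-joining
tree; larger values indicate reticulation, i.e. non-vertical
transmission. Summary statistics of the distance distribution itself
(Fisher–Pearson skew, Hartigan-style dip test of unimodality) describe
the degree of cultural amalgamation.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable

import numpy as np
from scipy import stats
from scipy.optimize import nnls
from scipy.spatial.distance import pdist, squareform

from ._rand import rng_from_seed
from .io import DistanceMatrix, read_newick


@dataclasses.dataclass
class SplitSystem:
    """Weighted circular split system.

    ``cycle`` is a circular ordering (indices into ``taxa``); every split
    is a frozenset of taxon indices forming a contiguous arc of the
    cycle, paired with a non-negative weight. ``fit`` is the fraction of
    squared distance explained by the split metric.
    """

    taxa: list[str]
    cycle: list[int]
    splits: list[tuple[frozenset[int], float]]
    fit: float

    def __post_init__(self) -> None:
        pos = {t: i for i, t in enumerate(self.cycle)}
        n = len(self.taxa)
        for side, w in self.splits:
            if w < 0:
                raise ValueError("split weights must be non-negative")
            if not (0 < len(side) < n):
                raise ValueError("split sides must be proper non-empty subsets")
            ps = sorted(pos[t] for t in side)
            if not _is_arc(ps, n):
                raise ValueError("split is not an arc of the cycle")

    def as_distance(self) -> np.ndarray:
        """The split metric: d(a,b) = sum of weights of splits separating them."""
        n = len(self.taxa)
        d = np.zeros((n, n))
        for side, w in self.splits:
            m = np.zeros(n, bool)
            m[list(side)] = True
            sep = m[:, None] ^ m[None, :]
            d += w * sep
        return d


def _is_arc(sorted_positions: list[int], n: int) -> bool:
    """Contiguous modulo n (a side is an arc iff its complement is)."""
    s = set(sorted_positions)
    breaks = sum(1 for p in s if (p + 1) % n not in s)
    return breaks <= 1


def archetype_distances(am) -> DistanceMatrix:
    """Euclidean distances between membership rows of an archetype model."""
    alpha = am.alpha
    ids = am.society_ids or [str(i) for i in range(alpha.shape[0])]
    return DistanceMatrix(taxa=list(ids), d=squareform(pdist(alpha)))


# ---------------------------------------------------------------------------
# Neighbor-Net


def _nn_ordering(D0: np.ndarray) -> list[int]:
    """Circular ordering by Neighbor-Net agglomeration.

    Maintains clusters of one or two linked nodes. Cluster pairs are
    chosen by the neighbour-joining criterion on cluster-averaged
    distances; the nodes to link are chosen by the same criterion over
    the nodes of the two clusters with all remaining clusters as units.
    Chains of three nodes are contracted to two with the standard 2/3–1/3
    distance reduction, recorded and re-expanded at the end.
    """
    n0 = D0.shape[0]
    cap = 3 * n0 + 4
    D = np.zeros((cap, cap))
    D[:n0, :n0] = D0
    active = list(range(n0))
    nxt = n0
    clusters: list[list[int]] = [[i] for i in range(n0)]
    reductions: list[tuple[int, int, tuple[int, int, int]]] = []

    def cdist(A: list[int], B: list[int]) -> float:
        return float(np.mean([D[a, b] for a in A for b in B]))

    while len(clusters) > 1:
        m = len(clusters)
        if m == 2:
            ci, cj = 0, 1
        else:
            CD = np.zeros((m, m))
            for a in range(m):
                for b in range(a + 1, m):
                    CD[a, b] = CD[b, a] = cdist(clusters[a], clusters[b])
            R = CD.sum(axis=1)
            best, ci, cj = np.inf, 0, 1
            for a in range(m):
                for b in range(a + 1, m):
                    q = (m - 2) * CD[a, b] - R[a] - R[b]
                    if q < best - 1e-14:
                        best, ci, cj = q, a, b
        A, B = clusters[ci], clusters[cj]
        others = [clusters[t] for t in range(len(clusters)) if t not in (ci, cj)]
        # choose which node of A links to which node of B
        if len(A) == 1 and len(B) == 1:
            x, y = A[0], B[0]
        else:
            ents: list[list[int]] = [[a] for a in A] + [[b] for b in B] + others
            mh = len(ents)
            ED = np.zeros((mh, mh))
            for a in range(mh):
                for b in range(a + 1, mh):
                    ED[a, b] = ED[b, a] = cdist(ents[a], ents[b])
            Rh = ED.sum(axis=1)
            best = np.inf
            x = y = -1
            for ia, a in enumerate(A):
                for ib, b in enumerate(B):
                    jb = len(A) + ib
                    q = (mh - 2) * ED[ia, jb] - Rh[ia] - Rh[jb]
                    if q < best - 1e-14:
                        best, x, y = q, a, b
        # chain the merged cluster with x adjacent to y
        chain = [z for z in A if z != x] + [x, y] + [z for z in B if z != y]
        clusters = [c for t, c in enumerate(clusters) if t not in (ci, cj)]

        while len(chain) > 2:
            z1, z2, z3 = chain[0], chain[1], chain[2]
            u, v = nxt, nxt + 1
            nxt += 2
            for t in active:
                if t in (z1, z2, z3):
                    continue
                D[u, t] = D[t, u] = (2.0 / 3.0) * D[z1, t] + (1.0 / 3.0) * D[z2, t]
                D[v, t] = D[t, v] = (1.0 / 3.0) * D[z2, t] + (2.0 / 3.0) * D[z3, t]
            duv = (D[z1, z2] + D[z2, z3] + D[z1, z3]) / 3.0
            D[u, v] = D[v, u] = duv
            # distances from u, v to the rest of the chain (if a 4th node remains)
            for t in chain[3:]:
                D[u, t] = D[t, u] = (2.0 / 3.0) * D[z1, t] + (1.0 / 3.0) * D[z2, t]
                D[v, t] = D[t, v] = (1.0 / 3.0) * D[z2, t] + (2.0 / 3.0) * D[z3, t]
            reductions.append((u, v, (z1, z2, z3)))
            for z in (z1, z2, z3):
                active.remove(z)
            active += [u, v]
            chain = [u, v] + chain[3:]
        clusters.append(chain)

    order = list(clusters[0])
    for u, v, (z1, z2, z3) in reversed(reductions):
        iu = order.index(u)
        iv = order.index(v)
        L = len(order)
        if (iu + 1) % L == iv:
            order[iu : iu + 1] = [z1, z2]
            order[order.index(v)] = z3
        elif (iv + 1) % L == iu:
            order[iv : iv + 1] = [z3, z2]
            order[order.index(u)] = z1
        else:  # should not happen; fall back to replacing in place
            order[iu] = z1
            order[iv : iv + 1] = [z2, z3]
    assert sorted(order) == list(range(n0)), "expansion lost taxa"
    return order


def _circular_split_members(cycle: list[int]) -> list[frozenset[int]]:
    """All splits whose side is a contiguous arc avoiding cycle position 0."""
    n = len(cycle)
    out = []
    for i in range(1, n):
        for j in range(i, n):
            out.append(frozenset(cycle[i : j + 1]))
    return out


def _split_design_matrix(splits: list[frozenset[int]], n: int) -> np.ndarray:
    pairs = np.array(list(itertools.combinations(range(n), 2)))
    A = np.zeros((len(pairs), len(splits)))
    for s, side in enumerate(splits):
        m = np.zeros(n, bool)
        m[list(side)] = True
        A[:, s] = m[pairs[:, 0]] ^ m[pairs[:, 1]]
    return A


def neighbor_net(dm: DistanceMatrix, weight_floor: float = 1e-9) -> SplitSystem:
    """Neighbor-Net split network of a distance matrix.

    Agglomeration yields a circular ordering; weights for all splits
    compatible with the ordering are then estimated by non-negative least
    squares against the observed distances, and splits below
    ``weight_floor`` are dropped. On an additive tree metric the recovered
    splits are the tree's edges with their branch lengths. For n of 2 or 3
    the (unique) trivial split decomposition is returned.
    """
    d = dm.d
    n = dm.n
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if n == 2:
        return SplitSystem(dm.taxa, [0, 1], [(frozenset([0]), float(d[0, 1]))], 1.0)
    if n == 3:
        w0 = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
        w1 = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
        w2 = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
        splits = [
            (frozenset([i]), max(float(w), 0.0))
            for i, w in zip(range(3), (w0, w1, w2))
        ]
        return SplitSystem(dm.taxa, [0, 1, 2], splits, 1.0)

    cycle = _nn_ordering(d)
    members = _circular_split_members(cycle)
    A = _split_design_matrix(members, n)
    iu = np.triu_indices(n, k=1)
    dvec = d[iu]
    w, rnorm = nnls(A, dvec)
    total = float(np.sum(dvec**2))
    fit = 1.0 - (rnorm**2) / total if total > 0 else 1.0
    splits = [
        (side, float(wi)) for side, wi in zip(members, w) if wi >= weight_floor
    ]
    return SplitSystem(dm.taxa, cycle, splits, float(fit))


def tree_splits(tree_or_newick) -> dict[frozenset[str], float]:
    """Edge-induced splits of a tree as {smaller-side tip labels: length}.

    Pendant edges give trivial splits. Sides are reported as the set not
    containing the first taxon, so they compare directly with Neighbor-Net
    output mapped to labels.
    """
    tree = tree_or_newick if hasattr(tree_or_newick, "leaf_node_iter") else read_newick(tree_or_newick)
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    first = sorted(all_tips)[0]
    out: dict[frozenset[str], float] = {}
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.head_node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        if len(below) in (0, len(all_tips)):
            continue
        side = below if first not in below else all_tips - below
        if len(side) == 0:
            continue
        out[side] = out.get(side, 0.0) + float(edge.length)
    return out


# ---------------------------------------------------------------------------
# tree-likeness


@dataclasses.dataclass
class TreeLikenessResult:
    mean_delta: float | None = None
    per_taxon_delta: np.ndarray | None = None
    mean_q_residual: float | None = None
    per_taxon_q: np.ndarray | None = None
    normalised: bool = True
    n_quartets: int = 0
    monte_carlo: bool = False


def _quartet_stats(
    d: np.ndarray,
    max_exhaustive_n: int = 200,
    n_subsample: int = 2_000_000,
    seed: int = 0,
) -> tuple[float, np.ndarray, float, np.ndarray, int, bool]:
    n = d.shape[0]
    delta_sum = 0.0
    q_sum = 0.0
    per_delta = np.zeros(n)
    per_q = np.zeros(n)
    count = 0
    monte_carlo = n > max_exhaustive_n

    def consume(quads: np.ndarray) -> None:
        nonlocal delta_sum, q_sum, count
        i, j, k, l = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
        sums = np.stack([d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]])
        sums.sort(axis=0)
        m3, m2, m1 = sums[0], sums[1], sums[2]
        spread = m1 - m3
        delta = np.where(spread > 0, (m1 - m2) / np.where(spread > 0, spread, 1.0), 0.0)
        q = (m1 - m2) ** 2
        delta_sum += float(delta.sum())
        q_sum += float(q.sum())
        for col in range(4):
            np.add.at(per_delta, quads[:, col], delta)
            np.add.at(per_q, quads[:, col], q)
        count += len(quads)

    if not monte_carlo:
        for i in range(n - 3):
            tail = np.array(list(itertools.combinations(range(i + 1, n), 3)))
            quads = np.column_stack([np.full(len(tail), i), tail])
            consume(quads)
    else:
        rng = rng_from_seed(seed)
        drawn = 0
        while drawn < n_subsample:
            block = min(200_000, n_subsample - drawn)
            cand = rng.integers(0, n, size=(block, 4))
            cand.sort(axis=1)
            ok = (np.diff(cand, axis=1) > 0).all(axis=1)
            consume(cand[ok])
            drawn += block
    if not monte_carlo:
        from math import comb

        per_count = np.full(n, comb(n - 1, 3))
    else:  # expected per-taxon count under uniform subsampling
        per_count = np.maximum(np.full(n, 4.0 * count / n), 1.0)
    return (
        delta_sum / count,
        per_delta / per_count,
        q_sum / count,
        per_q / per_count,
        count,
        monte_carlo,
    )


def delta_score(dm: DistanceMatrix, seed: int = 0) -> TreeLikenessResult:
    """Mean and per-taxon δ-scores over quartets.

    δ is scale-invariant; it is 0 exactly when every quartet satisfies
    the four-point condition. Quartets are enumerated exhaustively up to
    n = 200 and subsampled (seeded) beyond that.
    """
    if dm.n < 4:
        raise ValueError("δ-score needs at least 4 taxa")
    md, pd_, mq, pq, cnt, mc = _quartet_stats(dm.d, seed=seed)
    return TreeLikenessResult(
        mean_delta=md, per_taxon_delta=pd_, n_quartets=cnt, monte_carlo=mc
    )


def q_residual(dm: DistanceMatrix, normalise: bool = True, seed: int = 0) -> TreeLikenessResult:
    """Mean and per-taxon Q-residuals (m1 - m2)^2 over quartets.

    Q is magnitude-sensitive, so by default distances are rescaled to
    mean pairwise distance 1 before scoring.
    """
    if dm.n < 4:
        raise ValueError("Q-residual needs at least 4 taxa")
    d = dm.d
    if normalise:
        mean_d = dm.condensed().mean()
        if mean_d > 0:
            d = d / mean_d
    md, pd_, mq, pq, cnt, mc = _quartet_stats(d, seed=seed)
    return TreeLikenessResult(
        mean_q_residual=mq, per_taxon_q=pq, normalised=normalise, n_quartets=cnt, monte_carlo=mc
    )


def satisfies_four_point(dm: DistanceMatrix, tol: float = 1e-9) -> bool:
    """Brute-force four-point check over all quartets (small n only)."""
    d = dm.d
    for i, j, k, l in itertools.combinations(range(dm.n), 4):
        sums = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]])
        if sums[2] - sums[1] > tol:
            return False
    return True


# ---------------------------------------------------------------------------
# distance distribution statistics


def _prefix_convex_dev(xu: np.ndarray, f_lo: np.ndarray, f_up: np.ndarray) -> np.ndarray:
    """For each prefix length t, the largest gap between the ecdf and its
    greatest convex minorant over the first t+1 unique values."""
    m = len(xu)
    hull: list[int] = []
    dev = np.empty(m)
    for t in range(m):
        while len(hull) >= 2:
            i, j = hull[-2], hull[-1]
            if (f_lo[j] - f_lo[i]) * (xu[t] - xu[j]) >= (f_lo[t] - f_lo[j]) * (xu[j] - xu[i]):
                hull.pop()
            else:
                break
        hull.append(t)
        hx = xu[hull]
        hy = f_lo[hull]
        fit = np.interp(xu[: t + 1], hx, hy)
        dev[t] = float(np.max(f_up[: t + 1] - fit))
    return dev


def dip_statistic(x: np.ndarray) -> float:
    """Departure of a sample's ecdf from the best unimodal fit.

    The ecdf of a unimodal distribution is convex left of the mode and
    concave right of it; for every candidate mode the statistic takes the
    larger of the convex-side and concave-side maximal gaps (each halved,
    since an optimal fit splits the gap), minimised over modes. Zero-ish
    for unimodal samples, large for well-separated mixtures.
    """
    x = np.sort(np.asarray(x, float))
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 values")
    xu, counts = np.unique(x, return_counts=True)
    if len(xu) < 2:
        raise ValueError("all values identical; dip undefined")
    cum = np.cumsum(counts)
    f_up = cum / n
    f_lo = (cum - counts) / n
    conv = _prefix_convex_dev(xu, f_lo, f_up)
    # concave side via the reversal transform
    conc = _prefix_convex_dev(-xu[::-1], (1 - f_up)[::-1], (1 - f_lo)[::-1])[::-1]
    m = len(xu)
    best = np.inf
    for j in range(m):
        best = min(best, max(conv[j], conc[j]))
    return float(best / 2.0)


def distance_distribution_stats(
    dm: DistanceMatrix, dip_boot: int = 2000, seed: int = 0
) -> dict[str, float]:
    """Skew and unimodality of the pairwise distance distribution.

    Returns the adjusted Fisher–Pearson skew coefficient of the
    upper-triangle distances, the dip statistic, and a bootstrap p-value
    for unimodality from the uniform null (the dip is invariant to
    monotone transforms, so uniform draws of the same size serve as the
    null).
    """
    x = dm.condensed()
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct pairwise distances")
    skew = float(stats.skew(x, bias=False))
    dip = dip_statistic(x)
    rng = rng_from_seed(seed)
    null = np.empty(dip_boot)
    for b in range(dip_boot):
        null[b] = dip_statistic(rng.random(len(x)))
    p = float((null >= dip).mean())
    return {"skew": skew, "dip_statistic": dip, "dip_p": p}
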