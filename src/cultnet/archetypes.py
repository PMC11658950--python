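"""Archetypal analysis (PCHA) and clustering in the archetype space.

Archetypal analysis approximates a complete, centred data matrix X
(n societies x p traits) as

    X  ~  alpha @ beta.T @ X,

where each row of ``alpha`` (n x k) lies on the probability simplex —
``alpha[i, j]`` is the membership coefficient of society i in archetype
j — and each column of ``beta`` (n x k) lies on the simplex, so the
archetype profiles ``S = X.T @ beta`` (p x k) are convex combinations of
observed societies. Both blocks are optimised by projected gradient
descent with monotone (backtracking) steps from a furthest-sum start,
best of several restarts.

Because societies can share similar *mixtures* of archetypes, the number
of distinct clusters may exceed k; a K-means scan over nearby cluster
counts scored by three internal metrics decides this.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from ._rand import rng_from_seed


@dataclasses.dataclass
class ArchetypeModel:
    """Fitted PCHA factorisation (columns ordered by descending alpha mass)."""

    alpha: np.ndarray
    beta: np.ndarray
    S: np.ndarray
    sse: float
    explained_variance: float
    k: int
    seed: int
    sse_history: list[float]
    society_ids: list[str] | None = None

    def memberships(self) -> pd.DataFrame:
        idx = self.society_ids or [str(i) for i in range(self.alpha.shape[0])]
        return pd.DataFrame(
            self.alpha, index=idx, columns=[f"A{j + 1}" for j in range(self.k)]
        )


def simplex_project_rows(M: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = M.shape
    srt = np.sort(M, axis=1)[:, ::-1]
    css = np.cumsum(srt, axis=1) - 1.0
    idx = np.arange(1, k + 1)
    cond = srt - css / idx > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(M - theta[:, None], 0.0)


def _furthest_sum(X: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    """Furthest-sum seeding: spread initial archetype supports over the data."""
    n = X.shape[0]
    sq = np.einsum("ij,ij->i", X, X)

    def dist_to(j: int) -> np.ndarray:
        return np.sqrt(np.maximum(sq + sq[j] - 2 * X @ X[j], 0.0))

    chosen = [int(rng.integers(n))]
    total = dist_to(chosen[0])
    for _ in range(k - 1 if k > 1 else 0):
        total[chosen] = -np.inf
        nxt = int(np.argmax(total))
        chosen.append(nxt)
        total[chosen[-1]] = -np.inf
        total = np.where(np.isinf(total), total, total + dist_to(nxt))
    if k > 1:  # re-seat the arbitrary first pick
        first = chosen.pop(0)
        total = np.zeros(n)
        for j in chosen:
            total += dist_to(j)
        total[chosen] = -np.inf
        chosen.append(int(np.argmax(total)))
    return chosen[:k]


def _pg_block(
    var: np.ndarray,
    grad_fn,
    loss_fn,
    project,
    step: float,
    inner: int = 8,
) -> tuple[np.ndarray, float, float]:
    """Backtracking projected-gradient steps; loss never increases."""
    f = loss_fn(var)
    for _ in range(inner):
        g = grad_fn(var)
        improved = False
        for _ in range(30):
            cand = project(var - step * g)
            fc = loss_fn(cand)
            if fc <= f:
                improved = fc < f - 1e-18
                var, f = cand, fc
                step *= 1.2
                break
            step *= 0.5
        if not improved:
            break
    return var, f, step


def _fit_once(
    X: np.ndarray, k: int, tol: float, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    n = X.shape[0]
    beta = np.zeros((n, k))
    for c, idx in enumerate(_furthest_sum(X, k, rng)):
        beta[idx, c] = 1.0
    alpha = np.full((n, k), 1.0 / k)

    def loss(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.sum((X - a @ (b.T @ X)) ** 2))

    f = loss(alpha, beta)
    hist = [f]
    step_a, step_b = 1.0, 1.0
    for _ in range(max_iter):
        Z = beta.T @ X
        alpha, f, step_a = _pg_block(
            alpha,
            lambda a: 2.0 * (a @ Z - X) @ Z.T,
            lambda a: float(np.sum((X - a @ Z) ** 2)),
            simplex_project_rows,
            step_a,
        )
        beta, f, step_b = _pg_block(
            beta,
            lambda b: -2.0 * X @ (X - alpha @ (b.T @ X)).T @ alpha,
            lambda b: loss(alpha, b),
            lambda b: simplex_project_rows(b.T).T,
            step_b,
        )
        hist.append(f)
        if hist[-2] - hist[-1] < tol * (1.0 + hist[-2]):
            break
    return alpha, beta, f, hist


def fit_archetypes(
    X: np.ndarray,
    k: int,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int = 0,
    society_ids: list[str] | None = None,
) -> ArchetypeModel:
    """PCHA fit minimising ``||X - alpha beta^T X||^2`` under simplex
    constraints; best of ``n_restarts`` by residual sum of squares."""
    X = np.asarray(X, float)
    if np.isnan(X).any():
        raise ValueError("X must be complete (impute first)")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows n={n}")
    rng = rng_from_seed(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        alpha, beta, f, hist = _fit_once(X, k, tol, max_iter, rng)
        if best is None or f < best[2]:
            best = (alpha, beta, f, hist)
    alpha, beta, sse, hist = best

    order = np.argsort(-alpha.sum(axis=0), kind="stable")
    alpha, beta = alpha[:, order], beta[:, order]
    total = float(np.sum(X**2))
    ev = 1.0 - sse / total if total > 0 else 1.0
    return ArchetypeModel(
        alpha=alpha,
        beta=beta,
        S=X.T @ beta,
        sse=sse,
        explained_variance=float(min(max(ev, 0.0), 1.0)),
        k=k,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        sse_history=hist,
        society_ids=society_ids,
    )


@dataclasses.dataclass
class ClusterSelection:
    labels: np.ndarray
    n_clusters: int
    metrics: pd.DataFrame  # index = candidate count; silhouette, variance_ratio, davies_bouldin
    winner_votes: dict[int, int]


def scan_candidates(k: int) -> list[int]:
    """Cluster counts scanned for a model with k archetypes: k-2..k+2
    (floor 2), except k=2 scans 2..4."""
    if k < 2:
        raise ValueError("scan needs k >= 2")
    if k == 2:
        return [2, 3, 4]
    return list(range(max(2, k - 2), k + 3))


def select_from_metrics(metrics: pd.DataFrame, k: int) -> tuple[int, dict[int, int]]:
    """Apply the two-or-more-metrics rule to a metrics table.

    ``metrics`` is indexed by candidate count with columns ``silhouette``
    and ``variance_ratio`` (maximised) and ``davies_bouldin`` (minimised).
    Returns the selected count and the vote tally; when no candidate
    optimises at least two metrics the count falls back to k. Ties break
    toward the smaller candidate.
    """
    candidates = list(metrics.index)
    votes: dict[int, int] = {c: 0 for c in candidates}
    votes[candidates[int(np.argmax(metrics["silhouette"].to_numpy()))]] += 1
    votes[candidates[int(np.argmax(metrics["variance_ratio"].to_numpy()))]] += 1
    votes[candidates[int(np.argmin(metrics["davies_bouldin"].to_numpy()))]] += 1
    winners = [c for c, v in votes.items() if v >= 2]
    return (winners[0] if winners else k), votes


def select_num_kmeans_clusters(am: ArchetypeModel, seed: int = 0) -> ClusterSelection:
    """K-means scan around k scored by three internal metrics.

    Candidates run from k-2 to k+2 (floor 2), except k=2 scans 2..4. The
    silhouette score and variance-ratio (Calinski–Harabasz) criterion are
    maximised and the Davies–Bouldin index minimised; the selected count
    is the candidate optimal under at least two of the three metrics,
    falling back to k when the three disagree. Ties break toward the
    smaller count.
    """
    if am.k < 2:
        raise ValueError("cluster scan needs a model with k >= 2")
    n = am.alpha.shape[0]
    candidates = scan_candidates(am.k)
    feasible = [c for c in candidates if c <= n - 1]
    if feasible != candidates:
        warnings.warn(
            f"scan range shrunk to {feasible} (only {n} societies)", stacklevel=2
        )
        candidates = feasible
    if not candidates:
        raise ValueError("too few societies for any cluster count in the scan")

    rng = rng_from_seed(seed)
    rows = []
    fits = {}
    for c in candidates:
        km = KMeans(n_clusters=c, n_init=50, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(am.alpha)
        fits[c] = labels
        rows.append(
            {
                "n_clusters": c,
                "silhouette": silhouette_score(am.alpha, labels),
                "variance_ratio": calinski_harabasz_score(am.alpha, labels),
                "davies_bouldin": davies_bouldin_score(am.alpha, labels),
            }
        )
    metrics = pd.DataFrame(rows).set_index("n_clusters")

    selected, votes = select_from_metrics(metrics, am.k)
    if selected not in fits:  # fallback k outside the feasible scan
        selected = min(fits, key=lambda c: abs(c - selected))
    return ClusterSelection(
        labels=fits[selected], n_clusters=selected, metrics=metrics, winner_votes=votes
    )
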