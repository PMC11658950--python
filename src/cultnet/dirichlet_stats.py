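"""Dirichlet modelling of regional membership matrices.

A region's archetype memberships (rows on the simplex) are modelled as
draws from a region-specific Dirichlet distribution. Three inferential
tools build on the maximum-likelihood fit:

* a likelihood-ratio chi-square test of whether two regions share one
  Dirichlet (null M0, k parameters) or have distinct ones (M1, 2k
  parameters; df = k);
* a cultural-outlier test: across N posterior resamples of the data, the
  focal society's log-likelihood under a *reference* region's fit is
  compared with that under its *home* region's fit by a one-sided
  Mann–Whitney U test (reference stochastically dominant => the society
  is culturally closer to the reference region than to its neighbours);
* a normalised Fst-style summary of how differentiated membership rows
  are within a group — 0 when all rows coincide, 1 when every row sits
  on a simplex vertex — which tracks the Dirichlet variance.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import digamma, gammaln, polygamma

_EPS = 1e-6


@dataclasses.dataclass
class DirichletFit:
    concentration: np.ndarray
    loglik: float
    n_obs: int

    def __post_init__(self) -> None:
        if (self.concentration <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        if not np.isfinite(self.loglik):
            raise ValueError("non-finite log-likelihood")

    @property
    def mean(self) -> np.ndarray:
        return self.concentration / self.concentration.sum()


@dataclasses.dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    reject_at: float
    kind: str  # "lrt_chi2" | "mann_whitney_one_sided"

    @property
    def significant(self) -> bool:
        return self.p_value < self.reject_at


def clip_to_simplex_interior(memberships: np.ndarray, eps: float = _EPS) -> np.ndarray:
    """Clip rows into [eps, 1-eps] and renormalise (PCHA can emit exact 0s,
    which have infinite Dirichlet density gradient)."""
    M = np.clip(np.asarray(memberships, float), eps, 1.0 - eps)
    return M / M.sum(axis=1, keepdims=True)


def _inv_digamma(y: np.ndarray) -> np.ndarray:
    # Minka's initialisation followed by Newton steps
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y + 0.5772156649015329))
    for _ in range(5):
        x = x - (digamma(x) - y) / polygamma(1, x)
    return x


def dirichlet_loglik(memberships: np.ndarray, concentration: np.ndarray) -> float:
    """Total log density of (clipped) membership rows under Dir(concentration)."""
    P = clip_to_simplex_interior(np.atleast_2d(memberships))
    a = np.asarray(concentration, float)
    n = P.shape[0]
    return float(
        n * (gammaln(a.sum()) - gammaln(a).sum()) + ((a - 1.0) * np.log(P).sum(axis=0)).sum()
    )


def _moment_init(P: np.ndarray) -> np.ndarray:
    m = P.mean(axis=0)
    v = P.var(axis=0)
    ok = v > 1e-24  # rounding jitter from renormalisation is not real variance
    if not ok.any():
        raise ValueError("degenerate memberships: zero variance in every component")
    s = np.median(m[ok] * (1.0 - m[ok]) / v[ok] - 1.0)
    s = max(s, 1e-3)
    return np.maximum(m * s, 1e-3)


def _mean_loglik(a: np.ndarray, logp_bar: np.ndarray) -> float:
    return float(gammaln(a.sum()) - gammaln(a).sum() + ((a - 1.0) * logp_bar).sum())


def fit_dirichlet(
    memberships: np.ndarray,
    max_iter: int = 10000,
    tol: float = 1e-10,
    init: np.ndarray | None = None,
) -> DirichletFit:
    """Maximum-likelihood Dirichlet fit.

    A short run of Minka's fixed-point iteration (from a moment-matched
    start, or ``init`` to warm-start repeated fits) is polished by damped
    Newton steps, whose rank-one-plus-diagonal Hessian is inverted in
    closed form. Rows touching the simplex boundary are clipped inward
    and renormalised before fitting. Raises on fewer than two rows, on
    degenerate inputs and on non-convergence.
    """
    P = np.atleast_2d(np.asarray(memberships, float))
    if P.shape[0] < 2:
        raise ValueError("need at least 2 membership rows")
    if P.shape[1] < 2:
        raise ValueError("need k >= 2 components")
    P = clip_to_simplex_interior(P)
    logp_bar = np.log(P).mean(axis=0)
    a = np.asarray(init, float).copy() if init is not None else _moment_init(P)
    if (a <= 0).any():
        raise ValueError("init concentrations must be positive")

    for _ in range(20):
        a = _inv_digamma(digamma(a.sum()) + logp_bar)

    ll = _mean_loglik(a, logp_bar)
    converged = False
    for _ in range(200):
        g = digamma(a.sum()) - digamma(a) + logp_bar
        q = -polygamma(1, a)
        c = polygamma(1, a.sum())
        b = (g / q).sum() / (1.0 / c + (1.0 / q).sum())
        step = (g - b) / q
        t = 1.0
        for _ in range(40):
            a_new = a - t * step
            if (a_new > 0).all():
                ll_new = _mean_loglik(a_new, logp_bar)
                if ll_new >= ll - 1e-12:
                    break
            t *= 0.5
        else:
            break
        moved = np.max(np.abs(a_new - a))
        a, ll = a_new, ll_new
        if moved < tol * (1.0 + np.max(a)):
            converged = True
            break
    if not converged:
        # fall back to plain fixed-point iteration
        for it in range(max_iter):
            a_new = _inv_digamma(digamma(a.sum()) + logp_bar)
            if np.max(np.abs(a_new - a)) < tol * (1.0 + np.max(a)):
                a = a_new
                converged = True
                break
            a = a_new
        if not converged:
            raise RuntimeError("Dirichlet MLE did not converge")
    if not np.all(np.isfinite(a)) or (a <= 0).any():
        raise RuntimeError("Dirichlet MLE produced invalid concentrations")
    if a.sum() > 1e10:
        raise RuntimeError(
            "degenerate fit: concentrations diverge (sample variance ~ 0)"
        )
    return DirichletFit(concentration=a, loglik=dirichlet_loglik(P, a), n_obs=P.shape[0])


def region_test(A: np.ndarray, B: np.ndarray, sig: float = 0.05) -> TestResult:
    """Likelihood-ratio test of distinct regional Dirichlets.

    M0: both membership matrices are samples from one Dirichlet (k
    parameters); M1: each has its own (2k). The statistic
    2(l_M1 - l_M0) is referred to chi-square with df = k; p < sig means
    the two regions are significantly distinct. Symmetric in (A, B).
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("membership matrices must share k")
    k = A.shape[1]
    fit_a = fit_dirichlet(A)
    fit_b = fit_dirichlet(B)
    fit_0 = fit_dirichlet(np.vstack([A, B]))
    stat = 2.0 * (fit_a.loglik + fit_b.loglik - fit_0.loglik)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=k))
    return TestResult(statistic=stat, df=k, p_value=p, reject_at=sig, kind="lrt_chi2")


def outlier_test(
    posterior_membership_samples: np.ndarray,
    society_ids: Sequence[str],
    society_id: str,
    home_region: str,
    reference_region: str,
    region_of: Mapping[str, str],
    sig: float = 0.05,
) -> TestResult:
    """Is a society culturally closer to a reference region than to home?

    ``posterior_membership_samples`` is an (N, n, k) stack of membership
    matrices, one per posterior resample of the data; row order follows
    ``society_ids``. For every sample, Dirichlets are fitted to the
    reference and home regions (the focal society excluded from both) and
    the society's log-likelihood computed under each fit. The N reference
    and N home log-likelihoods are compared by a one-sided Mann–Whitney U
    test with the alternative that the reference log-likelihoods are
    stochastically dominant; p < sig flags a cultural outlier.
    """
    samples = np.asarray(posterior_membership_samples, float)
    if samples.ndim != 3:
        raise ValueError("expected an (N, n, k) stack of membership matrices")
    N, n, k = samples.shape
    if N < 20:
        raise ValueError("need N >= 20 posterior samples")
    ids = list(society_ids)
    if len(ids) != n:
        raise ValueError("society_ids length does not match sample rows")
    if region_of[society_id] != home_region:
        raise ValueError("society's region label must equal home_region")
    if home_region == reference_region:
        raise ValueError("home and reference regions must differ")
    focal = ids.index(society_id)
    home_idx = [i for i, s in enumerate(ids) if region_of[s] == home_region and i != focal]
    ref_idx = [i for i, s in enumerate(ids) if region_of[s] == reference_region and i != focal]
    if len(home_idx) < k + 1 or len(ref_idx) < k + 1:
        raise ValueError("a region has fewer than k+1 societies after excluding the focal one")

    ll_ref = np.empty(N)
    ll_home = np.empty(N)
    warm_ref = warm_home = None  # successive samples are similar; warm-start
    for s in range(N):
        M = samples[s]
        row = M[focal]
        fr = fit_dirichlet(M[ref_idx], init=warm_ref)
        fh = fit_dirichlet(M[home_idx], init=warm_home)
        warm_ref, warm_home = fr.concentration, fh.concentration
        ll_ref[s] = dirichlet_loglik(row, fr.concentration)
        ll_home[s] = dirichlet_loglik(row, fh.concentration)
    method = "asymptotic" if N >= 20 else "exact"
    res = stats.mannwhitneyu(ll_ref, ll_home, alternative="greater", method=method)
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        reject_at=sig,
        kind="mann_whitney_one_sided",
    )


def normalized_fst(memberships: np.ndarray) -> float:
    """Variance-based differentiation of membership rows, in [0, 1].

    Each archetype column is treated as an allele frequency q across
    societies; per column the ratio var(q) / (qbar (1 - qbar)) is computed
    and columns are combined by a qbar(1-qbar)-weighted mean. Identical
    rows give 0; rows that are all simplex vertices give 1. Zero-variance
    denominators are excluded (0 if every column is excluded).
    """
    P = np.atleast_2d(np.asarray(memberships, float))
    if P.shape[0] < 2:
        raise ValueError("need at least 2 membership rows")
    q = P.mean(axis=0)
    denom = q * (1.0 - q)
    keep = denom > 1e-12
    if not keep.any():
        return 0.0
    num = P.var(axis=0)[keep]
    return float(num.sum() / denom[keep].sum())
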