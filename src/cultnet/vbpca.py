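"""Variational Bayesian PCA for incomplete trait matrices.

The model is probabilistic PCA with missing data:

    y_ij = mu_j + w_j . s_i + eps,   eps ~ N(0, sigma^2)

with independent Gaussian posteriors over the loadings ``w_j`` (one per
variable) and scores ``s_i`` (one per society), an automatic-relevance
(per-component variance) prior on the loadings that switches superfluous
components off, and point estimates for the column means, noise variance
and relevance hyperparameters. Coordinate updates each maximise the
variational free energy exactly over their block, so the objective is
non-decreasing; the fitted model provides a per-entry posterior mean and
variance for the completed, centred matrix — including originally
missing cells — which downstream stages use for imputation, posterior
resampling and the eigenvalue test that picks the number of archetypes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._rand import rng_from_seed
from .io import TraitMatrix

_LOG2PI = np.log(2.0 * np.pi)
_V_FLOOR = 1e-12


@dataclasses.dataclass
class VbpcaModel:
    """Fitted posterior of the principal-subspace model.

    ``recon_mean``/``recon_var`` are the per-entry posterior predictive
    moments of the completed *centred* matrix (model uncertainty plus the
    estimated noise variance); ``eigenvalues`` are the component variances
    of the denoised reconstruction, sorted descending.
    """

    column_means: np.ndarray
    loadings_mean: np.ndarray
    loadings_var: np.ndarray
    scores_mean: np.ndarray
    scores_var: np.ndarray
    noise_variance: float
    recon_mean: np.ndarray
    recon_var: np.ndarray
    eigenvalues: np.ndarray
    component_relevance: np.ndarray
    free_energy: list[float]
    converged: bool
    n_iter: int
    mask: np.ndarray
    values: np.ndarray

    @property
    def d(self) -> int:
        return self.loadings_mean.shape[1]


def _spectrum(centred: np.ndarray) -> np.ndarray:
    """Eigenvalues of the sample covariance (descending), via singular values."""
    n = centred.shape[0]
    sv = np.linalg.svd(centred - centred.mean(axis=0), compute_uv=False)
    lam = sv**2 / max(n - 1, 1)
    full = np.zeros(min(centred.shape))
    full[: len(lam)] = lam
    return np.sort(full)[::-1]


def fit_vbpca(
    tm: TraitMatrix | np.ndarray,
    d_max: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int = 0,
) -> VbpcaModel:
    """Fit VBPCA to an incomplete matrix.

    Accepts a :class:`~cultnet.io.TraitMatrix` or a plain array with NaN
    for missing cells. ``d_max`` defaults to ``min(n, p) - 1`` capped at 30.
    Every row and column must have at least one observation (run the
    coverage filter first). Non-convergence within ``max_iter`` sets
    ``converged=False`` on the model rather than raising.
    """
    if isinstance(tm, TraitMatrix):
        Y, mask = tm.values, tm.mask
    else:
        Y = np.asarray(tm, float)
        mask = ~np.isnan(Y)
    n, p = Y.shape
    if not mask.any(axis=0).all():
        raise ValueError("a column has no observed values; filter coverage first")
    if not mask.any(axis=1).all():
        raise ValueError("a row has no observed values")
    if d_max is None:
        d_max = min(min(n, p) - 1, 30)
    if d_max > min(n, p) - 1:
        raise ValueError("d_max must be <= min(n, p) - 1")
    d = int(d_max)
    rng = rng_from_seed(seed)

    obs = mask
    Y0 = np.where(obs, Y, 0.0)
    n_obs_col = obs.sum(axis=0)
    n_total = int(obs.sum())

    mu = Y0.sum(axis=0) / n_obs_col
    filled = np.where(obs, Y, mu) - mu
    U, sv, Vt = np.linalg.svd(filled, full_matrices=False)
    Ms = (U[:, :d] * sv[:d]) + 1e-3 * rng.standard_normal((n, d))
    Mw = Vt[:d].T + 1e-3 * rng.standard_normal((p, d))
    Cs = np.tile(np.eye(d) * 1e-2, (n, 1, 1))
    Cw = np.tile(np.eye(d) * 1e-2, (p, 1, 1))
    sigma2 = max(float(np.var(filled)) * 0.1, 1e-4)
    v = np.full(d, 1.0)

    def expected_sq_resid() -> np.ndarray:
        # E[(y - mu - w.s)^2] for every cell (computed on all cells; callers mask)
        R = Y0 - mu - Ms @ Mw.T
        qw = np.einsum("jd,ide,je->ij", Mw, Cs, Mw, optimize=True)
        qs = np.einsum("id,jde,ie->ij", Ms, Cw, Ms, optimize=True)
        tt = np.einsum("iab,jab->ij", Cs, Cw, optimize=True)
        return R**2 + qw + qs + tt

    def free_energy(esq: float) -> float:
        f = -0.5 * n_total * (_LOG2PI + np.log(sigma2)) - esq / (2.0 * sigma2)
        # scores: E[log p(s)] - E[log q(s)]
        sign, logdet = np.linalg.slogdet(Cs)
        f += -0.5 * (np.sum(Ms**2) + np.einsum("idd->", Cs)) + 0.5 * logdet.sum()
        f += 0.5 * n * d  # entropy constant minus prior constant cancels the 2pi terms
        # loadings under ARD prior
        w2 = Mw**2 + np.einsum("jdd->jd", Cw)
        signw, logdetw = np.linalg.slogdet(Cw)
        f += -0.5 * (p * np.sum(np.log(v)) + np.sum(w2 / v)) + 0.5 * logdetw.sum()
        f += 0.5 * p * d
        return float(f)

    F_hist: list[float] = []
    converged = False
    Ww_outer = None
    for it in range(max_iter):
        # q(w_j) and its relevance variances, iterated jointly to their
        # mutual fixed point (still block ascent on F; speeds the collapse
        # of superfluous components)
        Ss_outer = np.einsum("ia,ib->iab", Ms, Ms) + Cs
        for _ in range(4):
            for j in range(p):
                rows = obs[:, j]
                B = np.diag(1.0 / v) + Ss_outer[rows].sum(axis=0) / sigma2
                Cw[j] = np.linalg.inv(B)
                Mw[j] = Cw[j] @ (Ms[rows].T @ (Y0[rows, j] - mu[j])) / sigma2
            v = np.maximum((Mw**2 + np.einsum("jdd->jd", Cw)).mean(axis=0), _V_FLOOR)
        # q(s_i)
        Ww_outer = np.einsum("ja,jb->jab", Mw, Mw) + Cw
        for i in range(n):
            cols = obs[i]
            A = np.eye(d) + Ww_outer[cols].sum(axis=0) / sigma2
            Cs[i] = np.linalg.inv(A)
            Ms[i] = Cs[i] @ (Mw[cols].T @ (Y0[i, cols] - mu[cols])) / sigma2
        # gauge: the scale split between w and s is a flat direction (v
        # absorbs it); the exact line maximum puts the scores' second
        # moment at the prior's, per component
        A2 = (Ms**2 + np.einsum("idd->id", Cs)).mean(axis=0)
        c = np.sqrt(np.maximum(A2, 1e-300))
        Ms /= c
        Mw *= c
        Cs /= c[None, :, None] * c[None, None, :]
        Cw *= c[None, :, None] * c[None, None, :]
        v = np.maximum((Mw**2 + np.einsum("jdd->jd", Cw)).mean(axis=0), _V_FLOOR)
        # point estimates
        fit_vals = Ms @ Mw.T
        mu = np.where(obs, Y0 - fit_vals, 0.0).sum(axis=0) / n_obs_col
        esq = float(expected_sq_resid()[obs].sum())
        sigma2 = max(esq / n_total, 1e-10)

        # drop components whose relevance has collapsed: their remaining
        # free-energy contribution is strictly negative, so removal only
        # raises the objective, and it stops them dragging out convergence
        if it >= 10 and d > 1:
            keep = v >= 1e-5 * v.max()
            if not keep.all():
                if not keep.any():
                    keep[int(np.argmax(v))] = True
                Ms, Mw, v = Ms[:, keep], Mw[:, keep], v[keep]
                Cs = Cs[:, keep][:, :, keep]
                Cw = Cw[:, keep][:, :, keep]
                d = int(keep.sum())

        F_hist.append(free_energy(esq))
        if it > 0:
            rel = (F_hist[-1] - F_hist[-2]) / (1.0 + abs(F_hist[-2]))
            if abs(rel) < tol:
                converged = True
                break

    recon_mean = Ms @ Mw.T
    qw = np.einsum("jd,ide,je->ij", Mw, Cs, Mw, optimize=True)
    qs = np.einsum("id,jde,ie->ij", Ms, Cw, Ms, optimize=True)
    tt = np.einsum("iab,jab->ij", Cs, Cw, optimize=True)
    recon_var = qw + qs + tt + sigma2
    eig = _spectrum(recon_mean)[:d]
    return VbpcaModel(
        column_means=mu,
        loadings_mean=Mw,
        loadings_var=np.einsum("jdd->jd", Cw).copy(),
        scores_mean=Ms,
        scores_var=np.einsum("idd->id", Cs).copy(),
        noise_variance=sigma2,
        recon_mean=recon_mean,
        recon_var=recon_var,
        eigenvalues=eig,
        component_relevance=v,
        free_energy=F_hist,
        converged=converged,
        n_iter=len(F_hist),
        mask=obs.copy(),
        values=np.where(obs, Y, np.nan),
    )


def impute(model: VbpcaModel, centred: bool = True) -> np.ndarray:
    """The completed matrix: posterior-mean reconstruction with no missing
    cells. The centred form is what archetypal analysis consumes; with
    ``centred=False`` the column means are added back."""
    out = model.recon_mean.copy()
    if not centred:
        out = out + model.column_means
    return out


def sample_posterior(model: VbpcaModel, N: int, seed: int = 0) -> np.ndarray:
    """``N`` completed centred matrices drawn entrywise from
    N(recon_mean, recon_var); reproducible by seed."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = rng_from_seed(seed)
    sd = np.sqrt(model.recon_var)
    return model.recon_mean + sd * rng.standard_normal((N,) + model.recon_mean.shape)


@dataclasses.dataclass
class ArchetypeNumberReport:
    """Outcome of the resampling eigenvalue test."""

    k: int
    n_significant: int
    observed: np.ndarray  # mean posterior-sample eigenvalues, descending
    null_quantiles: np.ndarray
    significant: np.ndarray  # consecutive-from-top significance flags
    exceeds: np.ndarray  # raw per-eigenvalue exceedance flags
    sig_level: float
    n_samples: int


def select_num_archetypes(
    model: VbpcaModel,
    N: int = 100,
    sig_level: float = 0.05,
    seed: int = 0,
) -> ArchetypeNumberReport:
    """Choose the number of archetypes k from the eigen-spectrum.

    The number of "large" covariance eigenvalues is expected to be k - 1.
    Rather than assuming a theoretical eigenvalue distribution, an
    empirical null is resampled: ``N`` completed matrices are drawn from
    the fitted posterior, and each is also column-permuted (independent
    permutation per column), which preserves every variable's marginal
    while destroying inter-variable covariance. Eigenvalue i is large when
    the mean observed i-th eigenvalue exceeds the (1 - sig_level) quantile
    of the i-th eigenvalues of the permuted matrices; large eigenvalues
    are counted consecutively from the top, and k = (#large) + 1.
    """
    if N < 20:
        raise ValueError("N must be >= 20 for a usable empirical null")
    rng = rng_from_seed(seed)
    samples = sample_posterior(model, N, seed=rng.integers(2**31 - 1))
    n, p = model.recon_mean.shape
    m = min(n, p)
    obs_spec = np.empty((N, m))
    null_spec = np.empty((N, m))
    for s in range(N):
        X = samples[s]
        obs_spec[s] = _spectrum(X)
        perm = np.empty_like(X)
        for j in range(p):
            perm[:, j] = X[rng.permutation(n), j]
        null_spec[s] = _spectrum(perm)
    observed = obs_spec.mean(axis=0)
    qs = np.quantile(null_spec, 1.0 - sig_level, axis=0)
    exceeds = observed > qs
    n_sig = 0
    for flag in exceeds:
        if not flag:
            break
        n_sig += 1
    significant = np.zeros(m, bool)
    significant[:n_sig] = True
    k = n_sig + 1
    return ArchetypeNumberReport(
        k=k,
        n_significant=n_sig,
        observed=observed,
        null_quantiles=qs,
        significant=significant,
        exceeds=exceeds,
        sig_level=sig_level,
        n_samples=N,
    )
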