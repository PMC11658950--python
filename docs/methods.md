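# Methods

`cultnet` analyses society × variable tables of integer-coded cultural
traits (the format of D-PLACE exports of the Ethnographic Atlas and
Pulotu) to ask two questions inspired by population genetics: *what are
the major mixtures ("archetypes") of cultural traits, and how vertical
was their transmission?* This note records the models, the numerical
choices, and what the bundled synthetic data can and cannot show.

## Data model and preprocessing

A trait table holds `n` societies by `p` variables, each variable either
ordinal (e.g. *degree of external conflict*, coded 1–4) or categorical,
with a missing mask. Variables belong to one of four cultural classes
(social organisation, subsistence, religion, cultural interaction) and
every class is analysed independently; a society with no observation in
a class is dropped from that class only.

Preprocessing choices:

- **Coverage filter.** Variables observed in fewer than 50% of societies
  are removed (configurable `min_fraction`); the remainder are imputed.
- **Encoding.** Ordinal variables enter as numeric columns; categorical
  variables are one-hot expanded over their declared level range, each
  indicator inheriting the parent cell's missing mask. The Euclidean
  machinery downstream (VBPCA, PCHA) assumes interval-like columns, and
  one-hot coding is the standard way to make multi-state nominal
  variables compatible with it. Treating categoricals as raw integers is
  the main alternative; it imposes an arbitrary order, so we do not use
  it.
- **Missing sentinel.** Empty CSV cells and a configurable sentinel
  (default `"NA"`) are missing.

## Imputation: variational Bayesian PCA

The completion model is probabilistic PCA on the observed cells,

    y_ij = mu_j + w_j · s_i + eps,   eps ~ N(0, sigma²),

with Gaussian variational posteriors over loadings `w_j` and scores
`s_i`, an automatic-relevance (per-component variance) prior on the
loadings, and point estimates (ML-II) for column means, noise variance
and relevance hyperparameters. Every coordinate update maximises the
variational free energy exactly over its block, so the objective is
non-decreasing by construction — the test suite asserts this per
iteration.

Numerical choices that matter:

- `d_max` defaults to `min(n, p) − 1` capped at 30; superfluous
  components are switched off by the relevance prior. Components whose
  relevance falls below `1e-5` of the largest are physically removed:
  their remaining free-energy contribution is strictly negative, so
  pruning only raises the objective, and it removes the slowly decaying
  tail that otherwise dominates run time.
- The scale split between loadings and scores is a nearly flat direction
  of the objective (the relevance variances absorb any rescaling). Each
  iteration therefore applies the closed-form gauge that puts the
  scores' second moment at the prior's (the exact line maximum along
  that direction); without it the fit needs thousands of iterations,
  with it a few dozen.
- Convergence: relative free-energy change below `tol` (default `1e-6`);
  non-convergence sets a flag on the model rather than raising.
- The per-entry reconstruction variance reported (and used for posterior
  sampling) is the posterior *predictive* variance: model uncertainty
  plus the estimated noise variance.

`impute` returns the mean-centred posterior-mean reconstruction — the
matrix `X` that archetypal analysis consumes. `sample_posterior` draws
completed matrices entrywise from N(recon_mean, recon_var).

## Number of archetypes

The number of "large" eigenvalues of the data covariance is expected to
equal `k − 1` for `k` archetypes (mixture weights sum to one, so
centring removes one dimension). Rather than assuming a theoretical
eigenvalue null, the test resamples: `N` completed matrices are drawn
from the VBPCA posterior; each is also column-permuted (an independent
permutation per column), which preserves every variable's marginal while
destroying inter-variable covariance. Eigenvalue `i` counts as large
when the mean `i`-th eigenvalue of the unpermuted samples exceeds the
`1 − sig_level` quantile of the `i`-th eigenvalues of the permuted ones;
large eigenvalues are counted consecutively from the top and
`k = #large + 1`. Comparing resampled spectra against resampled-permuted
spectra keeps the noise level identical on both sides of the
comparison. Pure-noise matrices yield `k = 1`; the pipeline floors the
archetype fit at `k = 2`, since a single corner is not a mixture model.

## Archetypal analysis (PCHA)

The factorisation approximates `X ≈ α βᵀ X` where rows of `α` (n × k)
and columns of `β` (n × k) lie on the probability simplex; `α_ij` is the
membership of society `i` in archetype `j` and `S = Xᵀβ` gives archetype
profiles as convex combinations of observed societies. Optimisation is
alternating projected gradient on each block (exact Euclidean simplex
projection, Armijo backtracking so the residual never increases), from a
furthest-sum seeding of the `β` support, best of `n_restarts = 10` by
residual. β's sparsity comes from the simplex projection itself; no
extra penalty is used. Archetype columns are re-ordered by descending
total membership so reports are reproducible. Restart counts and
tolerances are our defaults; they are not prescribed by the method
itself.

**Clusters in archetype space.** Societies with similar *mixtures* can
form more clusters than archetypes. K-means (50 restarts) scans counts
from `k − 2` to `k + 2` (floor 2; for `k = 2` the scan is 2–4), scored
by silhouette (max), variance-ratio (max) and Davies–Bouldin (min). The
count optimising at least two metrics wins; a three-way disagreement
falls back to `k`; ties break toward the smaller count (parsimony).

## Regional Dirichlet inference

Membership rows of a region are modelled as draws from a Dirichlet.
Fitting is maximum likelihood: a short Minka fixed-point run polished by
damped Newton steps (the Hessian is diagonal-plus-rank-one and inverted
in closed form); repeated fits warm-start from the previous optimum.
Rows touching the simplex boundary (PCHA can emit exact zeros) are
clipped to `[1e-6, 1 − 1e-6]` and renormalised before fitting. A sample
with zero variance in every component is reported as degenerate rather
than fitted.

- **Region distinctness.** Null M0: both regions share one Dirichlet
  (k parameters); alternative M1: two Dirichlets (2k). The statistic
  `2(ℓ_M1 − ℓ_M0)` is referred to chi-square with `df = k` — the
  parameter-count difference between the models.
- **Cultural outliers.** For a flagged society in a region significantly
  distinct from the reference region, the data matrix is resampled `N`
  times from the VBPCA posterior and archetypes refitted per sample
  (column order within a sample is irrelevant because both regional fits
  use the same sample). Per sample, Dirichlets are fitted to the
  reference and home regions *excluding the focal society from both* —
  the method itself does not dictate this, but including the society
  inflates its home likelihood — and its log-likelihood computed under
  each. The `N` reference vs `N` home log-likelihoods are compared by a
  one-sided Mann–Whitney U test (normal approximation with tie
  correction at `N ≥ 20`, exact below) with the alternative that the
  reference log-likelihoods are stochastically dominant; `p < 0.05`
  flags a cultural outlier. `N` defaults to 100 in the library and 25–30
  in the bundled configs, which simulation shows is already enough for
  the strong-separation regimes tested.
- **Normalised Fst.** Each archetype column is treated as an allele
  frequency `q` across societies; per column `var(q)/(q̄(1 − q̄))`,
  aggregated by a `q̄(1 − q̄)`-weighted mean. 0 for identical rows, 1
  when every row is a simplex vertex; decreasing in Dirichlet
  concentration (it tracks the Dirichlet variance).

## Distances, networks, tree-likeness

Cultural distance is the Euclidean distance between membership rows.
From the distance matrix:

- **Neighbor-Net.** Agglomerative selection (neighbour-joining criterion
  on cluster-averaged distances, then on the candidate nodes of the two
  chosen clusters) produces a circular ordering; chains of three nodes
  are contracted with the standard 2/3–1/3 reduction and re-expanded at
  the end. Weights for all `n(n−1)/2` splits compatible with the
  ordering are estimated by non-negative least squares against the
  observed distances; splits below `1e-9` are dropped. On additive tree
  metrics the recovered splits are exactly the tree's edges with their
  branch lengths (verified against the generating trees and against an
  independent implementation). The design matrix is `O(n⁴)` in memory,
  which is comfortable for the ≲ 100-society analyses the pipeline runs
  and is the reason split estimation is not attempted on much larger
  taxon sets. With `k = 2` archetypes the network degenerates to a
  two-branch tree, so the pipeline skips it with a note.
- **δ-score / Q-residual.** For every quartet the three pairwise-sum
  quantities are ordered `m1 ≥ m2 ≥ m3`; the quartet's
  `δ = (m1 − m2)/(m1 − m3)` (0 when `m1 = m3`) and `Q = (m1 − m2)²`.
  Both are averaged over all quartets for the headline value, and per
  taxon over the quartets containing it — the field sometimes averages
  per taxon first, so both conventions are emitted. δ is
  scale-invariant; Q is magnitude-sensitive and is therefore computed on
  distances normalised to mean 1 by default. Quartets are enumerated
  exhaustively up to n = 200 and subsampled (seeded, with the
  Monte-Carlo flag set on the result) beyond. Both statistics are zero
  exactly on additive metrics and grow with reticulation; low values
  indicate predominantly vertical transmission, but only as a relative,
  not absolute, measure.
- **Distance-distribution shape.** The adjusted Fisher–Pearson skew
  coefficient and a dip statistic of unimodality describe cultural
  amalgamation (a symmetric unimodal distance distribution suggests
  blending; skewed/multi-modal suggests distinct clusters). The dip is
  computed from the definition: the ecdf of a unimodal law is convex
  left of the mode and concave right of it, so for every candidate mode
  the statistic takes the larger of the two maximal gaps between the
  ecdf and its greatest convex minorant / least concave majorant (each
  halved, as the optimal fit splits a gap), minimised over modes. Its
  p-value is bootstrapped from the uniform null (the dip is invariant
  under monotone transforms, so uniform samples of the same size serve
  as the canonical unimodal null).

## Phylogenetic signal

Pagel's λ multiplies the off-diagonal entries of the Brownian
(shared-path-length) covariance of a trait over a supplied phylogeny;
λ = 1 is the full Brownian expectation, λ = 0 independence. The
ancestral mean and rate are profiled out analytically (GLS), λ is
maximised on [0, 1] by bounded scalar search with both endpoints
checked, and the p-value comes from chi-square(1) on the likelihood
ratio against λ = 0. Binary traits are analysed on the 0/1 scale with
the same continuous model — a documented stand-in, not a claim that a
threshold model would give identical estimates. Zero branch lengths are
floored at `1e-8`; a star phylogeny leaves λ unidentifiable and raises.
Estimates match the independent `phytools::phylosig` implementation on
simulated traits (cross-checked in the test suite).

## Synthetic data: what it emulates and what it does not

The generator mirrors the statistical structure the analysis assumes:
region-specific Dirichlet membership weights over `k` archetype
profiles, Gaussian trait noise, per-trait min–max quantisation onto
small integer scales (matching 1…L coding), independent-Bernoulli
missingness re-drawn per row so no society is entirely missing, and
injectable outlier societies whose memberships come from a foreign
region's Dirichlet while their region label stays put. Default study
conditions follow the shape of the real exports: ~130–150 societies in
3 regions, 24–40 variables per class, 4–6 ordinal levels, 10–20%
missing, strongly separated regional concentrations (e.g. Dir(8,1,1))
for power studies.

What it does **not** emulate: real coded data are not
Gaussian-noise-then-rounded (the true noise model is unknown);
missingness in ethnography is unlikely to be completely at random;
traits are generated exchangeably rather than with realistic
inter-variable semantics; and geography is absent (outlier status is an
input flag, not inferred from coordinates). Passing tests therefore show
that the pipeline recovers the structure it models, under its own
assumptions — not that those assumptions hold for any particular
empirical dataset.

## Problem sizes

Bundled configurations and checks run at 48–150 societies, 10–40
variables, 20–100 posterior resamples, and 100–1000 simulation
replicates per calibration estimate; these sizes give stable Monte-Carlo
estimates for the quantities reported while keeping a full run in the
minutes range on one core.

## Known limitations

- The eigenvalue-test null (per-sample independent column permutation)
  is one concrete choice among resampling schemes; it preserves
  marginals and destroys covariance but ignores any residual row
  structure.
- PCHA is non-convex; restarts mitigate but do not eliminate local
  optima, and `sse = 0` identities are met only to optimisation
  tolerance (~1e-8 relative).
- The Mann–Whitney outlier test conditions on the fitted archetype space
  of each posterior sample; uncertainty in `k` itself is not propagated.
- The dip statistic follows the unimodal-fit definition directly; it is
  used comparatively (bimodal vs unimodal, bootstrap p under the same
  statistic), and its absolute values are not interchangeable with other
  implementations'.
- Neighbor-Net split-weight estimation is dense NNLS and is quartic in
  taxon count; beyond a few hundred taxa it would need a sparse solver.
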