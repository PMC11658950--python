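# cultnet

Archetype-based analysis of cross-cultural trait matrices: who mixes
which cultural "archetypes", are regional mixtures distinct, which
societies are cultural outliers, and how tree-like — hence how
vertically transmitted — is the resulting cultural variation?

The package is aimed at cultural-evolution researchers working with
society × variable tables of integer-coded ordinal/categorical traits
in the style of D-PLACE exports (Ethnographic Atlas, Pulotu): ~100–150
societies, tens of variables per cultural class, substantial
missingness.

## What it computes

Given a trait matrix `X` (n societies × p traits, missing cells
allowed), per cultural class:

1. **Imputation / denoising** — variational Bayesian PCA over observed
   cells only, yielding a posterior mean and variance for every entry
   (including missing ones) and an automatic effective dimension.
2. **Number of archetypes** — the count of "large" covariance
   eigenvalues (expected to be k − 1) judged against an empirical null
   from posterior-resampled, column-permuted matrices.
3. **Archetypal analysis (PCHA)** — `X ≈ α βᵀ X` with rows of α and
   columns of β on the probability simplex, so each society is a convex
   mixture of archetypes and each archetype profile `S = Xᵀβ` is a
   convex mixture of societies; `α_ij` is the membership coefficient of
   society i in archetype j. K-means in the α space (scored by
   silhouette, variance-ratio and Davies–Bouldin) checks whether
   mixtures form more clusters than archetypes.
4. **Regional structure and outliers** — per-region Dirichlet fits to
   membership rows; a likelihood-ratio chi-square test of whether two
   regions share one Dirichlet; a posterior-resampled one-sided
   Mann–Whitney test for societies whose memberships are better
   explained by a reference region than by their neighbours; and a
   normalised Fst summarising within-region differentiation.
5. **Networks and verticality** — Euclidean distances between
   membership rows, a Neighbor-Net circular split system with
   non-negative least-squares weights (NEXUS output readable by split
   network viewers), and tree-likeness via δ-scores and Q-residuals:
   for each quartet the ordered pairwise-distance sums m1 ≥ m2 ≥ m3
   give δ = (m1 − m2)/(m1 − m3) and Q = (m1 − m2)²; both vanish exactly
   on additive (tree) metrics, and low values indicate predominantly
   vertical transmission. Distance-distribution skew and a dip test of
   unimodality quantify cultural amalgamation.
6. **Phylogenetic signal** — Pagel's λ for single traits over a
   supplied Newick phylogeny, with a chi-square(1) likelihood-ratio
   test against λ = 0.

A bundled synthetic-data generator produces trait tables with known
archetypes, regional Dirichlet memberships, injected outlier societies
and additive tree metrics, so the whole pipeline is testable without
downloading anything. See `docs/methods.md` for models, assumptions and
numerical details.

## Worked example

```python
from cultnet import (generate_cultural_dataset, inject_outliers, fit_vbpca,
                     select_num_archetypes, impute, fit_archetypes,
                     archetype_distances, delta_score, region_test, normalized_fst)

tm, truth = generate_cultural_dataset(
    n_per_region={"Polynesia": 20, "Micronesia": 20, "Melanesia": 20},
    p=30, k=3,
    region_params={"Polynesia": [8, 1, 1], "Micronesia": [1, 8, 1], "Melanesia": [1, 1, 8]},
    ordinal_levels=5, noise_sd=0.05, missing_rate=0.15, seed=42,
)
tm, truth = inject_outliers(tm, truth, ["s025"], donor_region="Polynesia", seed=1)

model = fit_vbpca(tm, seed=0)
report = select_num_archetypes(model, N=50, seed=1)
print(f"significant eigenvalues: {report.n_significant}  ->  k = {report.k}")

am = fit_archetypes(impute(model), report.k, seed=2, society_ids=tm.society_ids)
print(f"explained variance: {am.explained_variance:.3f}")

dm = archetype_distances(am)
print(f"mean delta-score: {delta_score(dm).mean_delta:.3f}")

regions = tm.society_meta["region"].to_numpy()
poly, micro = am.alpha[regions == "Polynesia"], am.alpha[regions == "Micronesia"]
res = region_test(poly, micro)
print(f"Polynesia vs Micronesia LRT: chi2 = {res.statistic:.1f} (df={res.df}), p = {res.p_value:.3g}")
print(f"Fst within Polynesia: {normalized_fst(poly):.3f}")
```

Output:

```
significant eigenvalues: 2  ->  k = 3
explained variance: 0.999
mean delta-score: 0.144
Polynesia vs Micronesia LRT: chi2 = 59.7 (df=3), p = 6.78e-13
Fst within Polynesia: 0.108
```

Reading it: two eigenvalues stand out against the resampled null, so
k = 3 archetypes (the mixture weights sum to one, which costs one
dimension after centring). The PCHA factorisation explains 99.9% of the
centred variance. The mean δ-score of 0.144 says the archetype-distance
network is fairly tree-like — unsurprising, as the generator draws each
region around its own archetype. The LRT rejects a shared Dirichlet for
Polynesia and Micronesia decisively, and the within-Polynesia Fst of
0.108 indicates modest internal differentiation.

The full per-class pipeline runs from one YAML config:

```sh
cultnet run --config analysis.yaml          # or: cultnet -v run ...
cultnet network --in distances.phy --out splits.nex --stats stats.json
cultnet signal --tree tree.nwk --trait headhunting.csv
```

writing `alpha_<class>.csv`, `profiles_<class>.csv`,
`distances_<class>.phy`, `splits_<class>.nex`, `report.json` and
`report.md` per class (classes with k = 2 skip the network stage, whose
split system would collapse to a two-branch tree).

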