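"""Synthetic cultural datasets with known archetype structure.

The generator emulates the statistical shape of cross-cultural trait
tables: ``n`` societies drawn from geographic regions, each society a
convex mixture of ``k`` latent archetype profiles with region-specific
Dirichlet membership weights; trait values are the mixture plus Gaussian
noise, quantised to small integer ordinal scales, with
missing-completely-at-random cells. "Polynesian-outlier"-style societies
— whose memberships come from a foreign region's distribution while
their region label stays put — can be injected so outlier detection has
a known answer. A companion routine produces additive (tree) metrics
with the generating Newick tree, giving a tree-likeness ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rand import rng_from_seed
from .io import DistanceMatrix, TraitMatrix, read_newick, tree_tip_distances


@dataclasses.dataclass
class GroundTruth:
    """Generating state of a synthetic dataset.

    ``true_memberships`` (n x k, rows on the simplex) and ``true_profiles``
    (p x k) are the mixture truth; ``region_params`` maps region name to its
    Dirichlet concentration vector; ``outlier_ids`` lists societies whose
    memberships were drawn from a foreign region. The quantisation affine
    (per-trait scale/offset), noise level and ordinal scales are retained so
    injected rows can be regenerated consistently.
    """

    true_memberships: np.ndarray
    true_profiles: np.ndarray
    region_params: dict[str, np.ndarray]
    region_of: dict[str, str]
    outlier_ids: set[str]
    seed: int
    noise_sd: float = 0.0
    ordinal_levels: np.ndarray | None = None
    col_scale: np.ndarray | None = None
    col_offset: np.ndarray | None = None
    quantise: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.true_memberships, float)
        if (a < -1e-12).any() or np.abs(a.sum(axis=1) - 1).max() > 1e-12:
            raise ValueError("true_memberships rows must lie on the simplex")
        for name, c in self.region_params.items():
            if (np.asarray(c) <= 0).any():
                raise ValueError(f"non-positive concentration for region {name!r}")
        if not set(self.outlier_ids) <= set(self.region_of):
            raise ValueError("outlier_ids must be a subset of society ids")

    def society_ids(self) -> list[str]:
        return list(self.region_of)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "true_memberships": self.true_memberships.tolist(),
            "true_profiles": self.true_profiles.tolist(),
            "region_params": {r: np.asarray(c).tolist() for r, c in self.region_params.items()},
            "region_of": self.region_of,
            "outlier_ids": sorted(self.outlier_ids),
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "ordinal_levels": None if self.ordinal_levels is None else self.ordinal_levels.tolist(),
            "col_scale": None if self.col_scale is None else self.col_scale.tolist(),
            "col_offset": None if self.col_offset is None else self.col_offset.tolist(),
            "quantise": self.quantise,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        arr = lambda x: None if x is None else np.asarray(x, float)
        return cls(
            true_memberships=np.asarray(obj["true_memberships"], float),
            true_profiles=np.asarray(obj["true_profiles"], float),
            region_params={r: np.asarray(c, float) for r, c in obj["region_params"].items()},
            region_of=dict(obj["region_of"]),
            outlier_ids=set(obj["outlier_ids"]),
            seed=int(obj["seed"]),
            noise_sd=float(obj["noise_sd"]),
            ordinal_levels=arr(obj["ordinal_levels"]),
            col_scale=arr(obj["col_scale"]),
            col_offset=arr(obj["col_offset"]),
            quantise=bool(obj["quantise"]),
        )


def _materialise_rows(
    alpha: np.ndarray, truth: GroundTruth, rng: np.random.Generator
) -> np.ndarray:
    """Trait values for membership rows using the stored generating map."""
    latent = alpha @ truth.true_profiles.T
    if truth.noise_sd > 0:
        latent = latent + rng.normal(0.0, truth.noise_sd, size=latent.shape)
    vals = latent * truth.col_scale + truth.col_offset
    if truth.quantise:
        levels = truth.ordinal_levels
        vals = np.clip(np.rint(vals), 1, levels)
    return vals


def generate_cultural_dataset(
    n_per_region: Mapping[str, int],
    p: int,
    k: int,
    region_params: Mapping[str, Sequence[float]],
    ordinal_levels: int | Sequence[int] = 4,
    noise_sd: float = 0.05,
    missing_rate: float = 0.0,
    seed: int = 0,
    quantise: bool = True,
    cultural_class: str = "social organisation",
    profile_sd: float = 1.0,
) -> tuple[TraitMatrix, GroundTruth]:
    """Simulate a society x trait table from a k-archetype mixture.

    Each society's membership row is drawn from its region's Dirichlet;
    latent trait values ``memberships @ profiles.T`` plus N(0, noise_sd)
    noise are min–max mapped per trait onto ``[1, L]`` and rounded to
    integers (skipped when ``quantise`` is False). An independent
    Bernoulli(``missing_rate``) mask is applied per cell, re-drawn per row
    until no society is fully missing.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    for r, c in n_per_region.items():
        if c < 1:
            raise ValueError(f"region {r!r} must have at least one society")
        if r not in region_params:
            raise ValueError(f"no Dirichlet parameters for region {r!r}")
    rng = rng_from_seed(seed)

    levels = np.broadcast_to(np.asarray(ordinal_levels, int), (p,)).copy()
    if (levels < 2).any():
        raise ValueError("every trait needs at least 2 ordinal levels")

    regions = list(n_per_region)
    n = sum(n_per_region.values())
    alpha = np.empty((n, k))
    region_of: dict[str, str] = {}
    row = 0
    for r in regions:
        conc = np.asarray(region_params[r], float)
        if conc.shape != (k,):
            raise ValueError(f"concentration for region {r!r} must have length k={k}")
        cnt = n_per_region[r]
        alpha[row : row + cnt] = rng.dirichlet(conc, size=cnt)
        for _ in range(cnt):
            region_of[f"s{row:03d}"] = r
            row += 1

    profiles = rng.normal(0.0, profile_sd, size=(p, k))
    latent = alpha @ profiles.T
    if noise_sd > 0:
        latent = latent + rng.normal(0.0, noise_sd, size=latent.shape)

    lo, hi = latent.min(axis=0), latent.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    scale = (levels - 1) / span
    offset = 1.0 - lo * scale
    vals = latent * scale + offset
    if quantise:
        vals = np.clip(np.rint(vals), 1, levels)

    mask = np.ones((n, p), dtype=bool)
    if missing_rate > 0:
        for i in range(n):
            while True:
                row_mask = rng.random(p) >= missing_rate
                if row_mask.any():
                    mask[i] = row_mask
                    break
    vals = np.where(mask, vals, np.nan)

    trait_meta = pd.DataFrame(
        {
            "name": [f"v{j:03d}" for j in range(p)],
            "cultural_class": cultural_class,
            "kind": "ordinal" if quantise else "continuous",
            "min_level": 1,
            "max_level": levels,
        }
    )
    ids = list(region_of)
    society_meta = pd.DataFrame(
        {
            "id": ids,
            "region": [region_of[s] for s in ids],
            "language_group": [region_of[s] for s in ids],
            "polynesian_outlier": False,
        }
    )
    tm = TraitMatrix(values=vals, mask=mask, trait_meta=trait_meta, society_meta=society_meta)
    truth = GroundTruth(
        true_memberships=alpha,
        true_profiles=profiles,
        region_params={r: np.asarray(c, float) for r, c in region_params.items()},
        region_of=region_of,
        outlier_ids=set(),
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        noise_sd=noise_sd,
        ordinal_levels=levels,
        col_scale=scale,
        col_offset=offset,
        quantise=quantise,
    )
    return tm, truth


def inject_outliers(
    tm: TraitMatrix,
    truth: GroundTruth,
    society_ids: Sequence[str],
    donor_region: str,
    seed: int = 0,
) -> tuple[TraitMatrix, GroundTruth]:
    """Turn listed societies into cultural outliers.

    Their membership rows are resampled from ``donor_region``'s Dirichlet
    and their trait values regenerated through the stored quantisation map;
    their region label is left unchanged (that is the point: the society
    sits in its home region but is culturally foreign). The existing
    missingness pattern is preserved. Returns updated copies.
    """
    if donor_region not in truth.region_params:
        raise ValueError(f"unknown donor region {donor_region!r}")
    ids = list(society_ids)
    all_ids = truth.society_ids()
    unknown = set(ids) - set(all_ids)
    if unknown:
        raise ValueError(f"unknown society id(s): {sorted(unknown)}")
    if not ids:
        return tm, truth
    rng = rng_from_seed(seed)
    idx = [all_ids.index(s) for s in ids]
    alpha = truth.true_memberships.copy()
    alpha[idx] = rng.dirichlet(truth.region_params[donor_region], size=len(idx))

    new_truth = dataclasses.replace(
        truth,
        true_memberships=alpha,
        outlier_ids=set(truth.outlier_ids) | set(ids),
    )
    vals = tm.values.copy()
    vals[idx] = _materialise_rows(alpha[idx], new_truth, rng)
    vals = np.where(tm.mask, vals, np.nan)
    smeta = tm.society_meta.copy()
    smeta.loc[smeta["id"].isin(ids), "polynesian_outlier"] = True
    new_tm = TraitMatrix(
        values=vals, mask=tm.mask.copy(), trait_meta=tm.trait_meta.copy(), society_meta=smeta
    )
    return new_tm, new_truth


# ---------------------------------------------------------------------------
# additive tree metrics


def _branch_sampler(
    law: str | Callable[[np.random.Generator], float],
) -> Callable[[np.random.Generator], float]:
    if callable(law):
        return law
    if law == "exponential":
        return lambda rng: float(rng.exponential(1.0))
    if law == "uniform":
        return lambda rng: float(rng.uniform(0.5, 1.5))
    if law == "unit":
        return lambda rng: 1.0
    raise ValueError(f"unknown branch length law {law!r}")


def generate_additive_tree_distances(
    n_taxa: int,
    branch_length_law: str | Callable[[np.random.Generator], float] = "exponential",
    seed: int = 0,
) -> tuple[DistanceMatrix, str]:
    """A random binary tree's path-length metric and its Newick string.

    The topology is built by joining uniformly random pairs of subtrees;
    every edge gets a strictly positive length from ``branch_length_law``
    (``"exponential"`` mean 1, ``"uniform"`` on (0.5, 1.5), ``"unit"``, or a
    callable). The returned metric is additive, so every quartet satisfies
    the four-point condition and its δ-score and Q-residual are zero.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = rng_from_seed(seed)
    draw = _branch_sampler(branch_length_law)

    def edge() -> float:
        b = draw(rng)
        if b <= 0:
            raise ValueError("branch lengths must be strictly positive")
        return b

    subtrees = [f"t{i}" for i in range(n_taxa)]
    while len(subtrees) > 2:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        merged = f"({a}:{edge():.10f},{b}:{edge():.10f})"
        subtrees = [s for t, s in enumerate(subtrees) if t not in (i, j)] + [merged]
    newick = f"({subtrees[0]}:{edge():.10f},{subtrees[1]}:{edge():.10f});"
    tree = read_newick(newick)
    dm = tree_tip_distances(tree)
    return dm, newick
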