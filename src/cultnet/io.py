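"""Reading and writing cross-cultural trait tables and phylogenetic exchange formats.

Trait tables follow the flat-CSV style of D-PLACE exports: a wide
society x variable matrix of small integer codes with empty cells (or a
sentinel such as ``"NA"``) marking missing values, plus two metadata
tables — one per variable (cultural class, ordinal/categorical kind,
coded value range) and one per society (region, language group, and a
flag for linguistically attested Polynesian outliers).

Distance matrices are exchanged as square PHYLIP, split systems as a
SplitsTree-compatible NEXUS ``ST_SPLITS`` block, and trees as Newick.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

CULTURAL_CLASSES = (
    "social organisation",
    "subsistence",
    "religion",
    "cultural interaction",
)

TRAIT_META_COLUMNS = ["name", "cultural_class", "kind", "min_level", "max_level"]
SOCIETY_META_COLUMNS = ["id", "region", "language_group", "polynesian_outlier"]


@dataclasses.dataclass
class TraitMatrix:
    """Society x variable integer-coded trait table with a missing mask.

    Attributes
    ----------
    values : (n, p) float array
        Integer codes stored as floats; cells where ``mask`` is False hold NaN.
    mask : (n, p) bool array
        True where a value was observed.
    trait_meta : DataFrame
        One row per column of ``values``; columns ``name``, ``cultural_class``,
        ``kind`` (``ordinal`` or ``categorical``), ``min_level``, ``max_level``.
    society_meta : DataFrame
        One row per row of ``values``; columns ``id``, ``region``,
        ``language_group``, ``polynesian_outlier``.
    """

    values: np.ndarray
    mask: np.ndarray
    trait_meta: pd.DataFrame
    society_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if len(self.trait_meta) != self.values.shape[1]:
            raise ValueError("trait_meta length does not match number of columns")
        if len(self.society_meta) != self.values.shape[0]:
            raise ValueError("society_meta length does not match number of rows")
        ids = self.society_meta["id"].tolist()
        if len(set(ids)) != len(ids):
            raise ValueError("society ids are not unique")
        self._check_ranges()

    def _check_ranges(self) -> None:
        vals = self.values
        for j, row in enumerate(self.trait_meta.itertuples(index=False)):
            obs = self.mask[:, j]
            if not obs.any():
                continue
            v = vals[obs, j]
            if row.kind == "ordinal" and (
                (v < row.min_level).any() or (v > row.max_level).any()
            ):
                bad = int(np.where(obs)[0][(v < row.min_level) | (v > row.max_level)][0])
                raise ValueError(
                    f"value out of declared range [{row.min_level}, {row.max_level}] "
                    f"at society {self.society_meta['id'].iloc[bad]!r}, "
                    f"variable {self.trait_meta['name'].iloc[j]!r}"
                )

    @property
    def n_societies(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def society_ids(self) -> list[str]:
        return self.society_meta["id"].tolist()

    @property
    def trait_names(self) -> list[str]:
        return self.trait_meta["name"].tolist()

    def coverage(self) -> np.ndarray:
        """Observed fraction per column."""
        return self.mask.mean(axis=0)

    def subset_class(self, cultural_class: str, drop_empty_rows: bool = True) -> "TraitMatrix":
        """Columns of one cultural class; societies with no observation in the
        class are dropped from that class's analysis only."""
        keep_cols = (self.trait_meta["cultural_class"] == cultural_class).to_numpy()
        if not keep_cols.any():
            raise ValueError(f"no variables in cultural class {cultural_class!r}")
        mask = self.mask[:, keep_cols]
        keep_rows = mask.any(axis=1) if drop_empty_rows else np.ones(len(mask), bool)
        return TraitMatrix(
            values=self.values[np.ix_(keep_rows, keep_cols)],
            mask=mask[keep_rows],
            trait_meta=self.trait_meta.loc[keep_cols].reset_index(drop=True),
            society_meta=self.society_meta.loc[keep_rows].reset_index(drop=True),
        )


@dataclasses.dataclass
class DistanceMatrix:
    """Pairwise distances with labelled taxa (symmetric, zero diagonal)."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")
        # exact symmetry and zero diagonal after validation
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]


# ---------------------------------------------------------------------------
# trait table CSV round trip


def _parse_cell(raw: str, sentinel: str) -> float:
    s = raw.strip()
    if s == "" or s == sentinel:
        return np.nan
    return float(int(float(s)))


def read_trait_table(
    values_path: str | Path,
    trait_meta_path: str | Path,
    society_meta_path: str | Path,
    missing_sentinel: str = "NA",
) -> TraitMatrix:
    """Read a wide society x variable CSV plus its two metadata tables.

    The first column of the values table holds society ids; remaining column
    headers are variable names. Empty cells and ``missing_sentinel`` become
    missing. Metadata are joined by variable name and society id; observed
    ordinal values outside the declared range raise a ``ValueError`` naming
    the offending row and column.
    """
    raw = pd.read_csv(values_path, dtype=str, keep_default_na=False)
    id_col = raw.columns[0]
    society_ids = raw[id_col].tolist()
    if len(set(society_ids)) != len(society_ids):
        dupes = {s for s in society_ids if society_ids.count(s) > 1}
        raise ValueError(f"duplicate society id(s): {sorted(dupes)}")
    trait_names = list(raw.columns[1:])
    values = np.full((len(society_ids), len(trait_names)), np.nan)
    for j, name in enumerate(trait_names):
        values[:, j] = [_parse_cell(c, missing_sentinel) for c in raw[name]]
    mask = ~np.isnan(values)

    tmeta = pd.read_csv(trait_meta_path)
    tmeta = tmeta.set_index("name").loc[trait_names].reset_index()
    tmeta["min_level"] = tmeta["min_level"].astype(int)
    tmeta["max_level"] = tmeta["max_level"].astype(int)

    smeta = pd.read_csv(society_meta_path)
    smeta["id"] = smeta["id"].astype(str)
    smeta = smeta.set_index("id").loc[society_ids].reset_index()
    smeta["polynesian_outlier"] = smeta["polynesian_outlier"].astype(bool)
    return TraitMatrix(values=values, mask=mask, trait_meta=tmeta, society_meta=smeta)


def write_trait_table(
    tm: TraitMatrix,
    values_path: str | Path,
    trait_meta_path: str | Path,
    society_meta_path: str | Path,
    missing_sentinel: str = "",
) -> None:
    """Write a TraitMatrix in the CSV dialect :func:`read_trait_table` reads."""
    rows = []
    for i, sid in enumerate(tm.society_ids):
        row = {"id": sid}
        for j, name in enumerate(tm.trait_names):
            row[name] = (
                str(int(round(tm.values[i, j]))) if tm.mask[i, j] else missing_sentinel
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(values_path, index=False)
    tm.trait_meta[TRAIT_META_COLUMNS].to_csv(trait_meta_path, index=False)
    smeta = tm.society_meta[SOCIETY_META_COLUMNS].copy()
    pd.DataFrame(smeta).to_csv(society_meta_path, index=False)


def filter_by_coverage(tm: TraitMatrix, min_fraction: float = 0.5) -> TraitMatrix:
    """Drop variables observed in fewer than ``min_fraction`` of societies.

    Retained variables all have coverage >= ``min_fraction`` and are the ones
    later completed by imputation. Idempotent; never alters retained values.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    keep = tm.coverage() >= min_fraction
    if not keep.any():
        raise ValueError("coverage filter removed every variable")
    return TraitMatrix(
        values=tm.values[:, keep],
        mask=tm.mask[:, keep],
        trait_meta=tm.trait_meta.loc[keep].reset_index(drop=True),
        society_meta=tm.society_meta.copy().reset_index(drop=True),
    )


def expand_categorical(tm: TraitMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Numeric design matrix for Euclidean analyses.

    Ordinal variables are kept as single numeric columns; categorical
    variables are one-hot expanded over their declared level range (the
    indicator inherits the parent cell's missing mask). Returns
    ``(values, mask, column_names)``.
    """
    cols: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    names: list[str] = []
    for j, row in enumerate(tm.trait_meta.itertuples(index=False)):
        name = tm.trait_meta["name"].iloc[j]
        if row.kind == "categorical":
            for level in range(int(row.min_level), int(row.max_level) + 1):
                cols.append(np.where(tm.mask[:, j], (tm.values[:, j] == level) * 1.0, np.nan))
                masks.append(tm.mask[:, j].copy())
                names.append(f"{name}={level}")
        else:
            cols.append(tm.values[:, j].copy())
            masks.append(tm.mask[:, j].copy())
            names.append(name)
    return np.column_stack(cols), np.column_stack(masks), names


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices


def write_distance_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance format (full precision, deterministic bytes)."""
    lines = [f"{dm.n}"]
    for name, row in zip(dm.taxa, dm.d):
        label = name.replace(" ", "_")
        lines.append(label + "  " + "  ".join(f"{x:.12g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_distance_phylip(path: str | Path) -> DistanceMatrix:
    text = Path(path).read_text().strip().splitlines()
    n = int(text[0].split()[0])
    taxa: list[str] = []
    rows: list[list[float]] = []
    for line in text[1 : n + 1]:
        parts = line.split()
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if len(rows) != n or any(len(r) != n for r in rows):
        raise ValueError("ragged or truncated PHYLIP distance matrix")
    return DistanceMatrix(taxa=taxa, d=np.array(rows))


# ---------------------------------------------------------------------------
# NEXUS splits output (SplitsTree-compatible)


def write_splits_nexus(ss, path: str | Path) -> None:
    """Write a split system as a NEXUS file with TAXA and ST_SPLITS blocks.

    ``ss`` needs attributes ``taxa`` (ordered labels), ``cycle`` (circular
    ordering as indices into ``taxa``), ``splits`` (list of
    ``(frozenset-of-indices, weight)``) and ``fit`` (fraction in [0, 1]).
    Taxa are numbered 1..n in the order of ``ss.taxa``, as split-network
    viewers expect.
    """
    n = len(ss.taxa)
    out = ["#nexus", "", "BEGIN Taxa;", f"DIMENSIONS ntax={n};", "TAXLABELS"]
    for i, name in enumerate(ss.taxa, start=1):
        out.append(f"[{i}] '{name}'")
    out += [";", "END; [Taxa]", ""]
    nsplits = len(ss.splits)
    out += [
        "BEGIN Splits;",
        f"DIMENSIONS ntax={n} nsplits={nsplits};",
        "FORMAT labels=no weights=yes confidences=no intervals=no;",
        f"PROPERTIES fit={100.0 * ss.fit:.2f} weighted;",
        "CYCLE " + " ".join(str(i + 1) for i in ss.cycle) + ";",
        "MATRIX",
    ]
    for idx, (side, w) in enumerate(ss.splits, start=1):
        members = " ".join(str(i + 1) for i in sorted(side))
        out.append(f"[{idx}, size={len(side)}] \t {w:.10g} \t {members},")
    out += [";", "END; [Splits]", ""]
    Path(path).write_text("\n".join(out))


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a Newick tree (file path or literal string) with branch lengths."""
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=s, schema="newick")
    else:
        tree = dendropy.Tree.get(path=s, schema="newick")
    return tree


def tree_tip_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length distances between the tips of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [t.label for t in tree.taxon_namespace]
    n = len(taxa)
    d = np.zeros((n, n))
    for i, ti in enumerate(tree.taxon_namespace):
        for j, tj in enumerate(tree.taxon_namespace):
            if i < j:
                d[i, j] = d[j, i] = pdm.patristic_distance(ti, tj)
    return DistanceMatrix(taxa=taxa, d=d)
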