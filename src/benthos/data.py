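"""Core domain containers and text-format I/O.

Every downstream stage consumes one of four objects defined here: an
:class:`OtuTable` (integer counts, samples x taxa), a :class:`PhyloTree`
(rooted, branch lengths, tips = taxon ids), an :class:`EnvTable`
(samples x environmental factors) and a :class:`GroupMap` (sample ->
group label).  Readers normalise orientation and validate invariants on
construction; malformed input is a hard error, never silently repaired.

All tabular formats are tab-separated text with one header row and one id
column; trees are newick.  Binary formats (BIOM, etc.) are out of scope.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "PhyloTree",
    "EnvTable",
    "GroupMap",
    "read_otu_table",
    "read_env_table",
    "read_group_map",
    "read_tree",
    "rarefy",
]


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} id: {lab!r}")
        seen.add(lab)


@dataclass
class OtuTable:
    """Integer OTU count matrix, canonical orientation samples x taxa.

    Parameters
    ----------
    counts
        DataFrame with sample ids as the index and taxon ids as columns.
        Values must be finite, non-negative integers.
    taxonomy
        Optional map ``taxon_id -> lineage string``.
    """

    counts: pd.DataFrame
    taxonomy: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.counts.size == 0:
            raise ValueError("empty OTU table")
        _check_unique(list(self.counts.index), "sample")
        _check_unique(list(self.counts.columns), "taxon")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("OTU counts must be finite")
        if (values < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("OTU counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by per-sample totals (rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValueError(f"sample(s) with zero total count: {bad}")
        return self.counts.div(totals, axis=0)

    def select_taxa(self, taxon_ids: Sequence[str]) -> "OtuTable":
        missing = [t for t in taxon_ids if t not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown taxon id(s): {missing}")
        sub = self.counts.loc[:, list(taxon_ids)].copy()
        tax = None
        if self.taxonomy is not None:
            tax = {t: self.taxonomy[t] for t in taxon_ids if t in self.taxonomy}
        return OtuTable(sub, taxonomy=tax)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return OtuTable(self.counts.loc[list(sample_ids)].copy(), taxonomy=self.taxonomy)

    def write(self, path: str | Path, orientation: str = "samples") -> None:
        df = self.counts if orientation == "samples" else self.counts.T
        df.to_csv(path, sep="\t", index_label="id")


@dataclass
class EnvTable:
    """Environmental parameters, samples x factors, no missing values."""

    values: pd.DataFrame
    units: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise ValueError("empty environmental table")
        _check_unique(list(self.values.index), "sample")
        _check_unique(list(self.values.columns), "factor")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            bad = self.values.columns[np.isnan(arr).any(axis=0)].tolist()
            raise ValueError(f"missing values in environmental factor(s): {bad}")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="id")


@dataclass
class GroupMap:
    """Sample -> group label assignment."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}
        if not self.mapping:
            raise ValueError("empty group map")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mapping)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.mapping.values():
            if g not in seen:
                seen.append(g)
        return seen

    def group_of(self, sample_id: str) -> str:
        try:
            return self.mapping[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} has no group assignment") from None

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.mapping.items():
            out.setdefault(g, []).append(s)
        return out

    def labels_for(self, sample_ids: Sequence[str]) -> list[str]:
        return [self.group_of(s) for s in sample_ids]

    def write(self, path: str | Path) -> None:
        pd.Series(dict(self.mapping), name="group").rename_axis("id").to_csv(path, sep="\t")


class PhyloTree:
    """Rooted phylogeny with branch lengths; tips are taxon ids.

    Thin wrapper around a :class:`dendropy.Tree` adding validation
    (unique tips, no missing branch lengths) and a cached patristic
    distance matrix.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._dist: pd.DataFrame | None = None
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        _check_unique(labels, "tip")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has edges without branch lengths")
            if edge.length < 0:
                raise ValueError("negative branch length")
        self._tips = labels

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"unparseable newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    # -- basic access --------------------------------------------------
    @property
    def tip_names(self) -> list[str]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip() + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    # -- distances -----------------------------------------------------
    def distance_matrix(self) -> pd.DataFrame:
        """Patristic (sum of branch lengths) distances between all tips."""
        if self._dist is None:
            pdm = self._tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in self._tree.taxon_namespace if t.label in set(self._tips)}
            n = len(self._tips)
            arr = np.zeros((n, n))
            for i, a in enumerate(self._tips):
                for j in range(i + 1, n):
                    d = pdm.patristic_distance(taxa[a], taxa[self._tips[j]])
                    arr[i, j] = arr[j, i] = d
            self._dist = pd.DataFrame(arr, index=self._tips, columns=self._tips)
        return self._dist

    def prune_to(self, taxon_ids: Sequence[str]) -> "PhyloTree":
        missing = [t for t in taxon_ids if t not in set(self._tips)]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        sub = self._tree.extract_tree_with_taxa_labels(list(taxon_ids))
        return PhyloTree(sub)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    return df


def read_otu_table(path: str | Path, orientation: str = "samples") -> OtuTable:
    """Read a tab-separated OTU table.

    ``orientation`` is ``"samples"`` when rows are samples (canonical) or
    ``"taxa"`` when rows are taxa; the result is always samples x taxa.
    """
    if orientation not in ("samples", "taxa"):
        raise ValueError("orientation must be 'samples' or 'taxa'")
    df = _read_tsv(path)
    if df.size == 0:
        raise ValueError("empty OTU table")
    # duplicated labels must be caught before pandas mangles them
    raw_index = pd.read_csv(path, sep="\t", usecols=[0]).iloc[:, 0].astype(str)
    _check_unique(raw_index.tolist(), "taxon" if orientation == "taxa" else "sample")
    if orientation == "taxa":
        df = df.T
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric counts in OTU table: {exc}") from exc
    return OtuTable(numeric)


def read_env_table(path: str | Path) -> EnvTable:
    df = _read_tsv(path)
    return EnvTable(df.apply(pd.to_numeric))


def read_group_map(path: str | Path) -> GroupMap:
    df = _read_tsv(path)
    if df.shape[1] != 1:
        raise ValueError("group map must have exactly one label column")
    return GroupMap(df.iloc[:, 0].astype(str).to_dict())


def read_tree(path: str | Path) -> PhyloTree:
    return PhyloTree.from_file(path)


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to ``depth`` individuals without replacement.

    Uses a multivariate hypergeometric draw per sample, so taxon support
    never grows and all row totals equal ``depth`` exactly.  Reproducible
    under a fixed ``seed``.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.sample_totals()
    if depth > int(totals.min()):
        raise ValueError(
            f"depth {depth} exceeds the smallest sample total ({int(totals.min())})"
        )
    rng = np.random.default_rng(seed)
    rows = [
        rng.multivariate_hypergeometric(row, depth)
        for row in table.counts.to_numpy()
    ]
    out = pd.DataFrame(rows, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(out, taxonomy=table.taxonomy)
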