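"""Readers, writers, and validated containers for the pipeline's file formats.

Three plain-text formats are supported: a tab-delimited OTU count table
(samples as rows by default), a Newick phylogeny over OTU identifiers, and a
tab-delimited sample-metadata table carrying grid coordinates and named
environmental covariates grouped into blocks.

Relative abundances are never stored: they are recomputed from counts
(row-normalised) wherever a statistic needs them, so every stage sees one
canonical normalisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("genspec")

#: Default grouping of metadata covariates into latent blocks: canopy cover
#: (CC), scattered radiation (SR) and light transmittance (LT) form the light
#: block; basal area (BA) and stand density (DEN) the plant block; aspect
#: (ASP) the topography block.
DEFAULT_BLOCKS: dict[str, tuple[str, ...]] = {
    "light": ("CC", "SR", "LT"),
    "plant": ("BA", "DEN"),
    "topography": ("ASP",),
}


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class OtuTable:
    """Nonnegative integer count matrix, samples x OTUs.

    Parameters
    ----------
    counts
        2-D integer array, one row per sample, one column per OTU.
    sample_ids, otu_ids
        Unique identifiers aligned to the rows / columns of ``counts``.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        validate_table(self)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised counts (each sample sums to 1)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        return self.counts / totals

    def presence_absence(self) -> np.ndarray:
        """Binary occurrence matrix (samples x OTUs)."""
        return (self.counts > 0).astype(np.int64)

    def richness(self) -> np.ndarray:
        """Observed richness (number of OTUs with count > 0) per sample."""
        return (self.counts > 0).sum(axis=1)

    def drop_empty_otus(self) -> "OtuTable":
        """Return a table without all-zero OTU columns (warns if any dropped)."""
        keep = self.counts.sum(axis=0) > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("dropping %d OTUs with zero total count", n_dropped)
            return self.subset_otus([o for o, k in zip(self.otu_ids, keep) if k])
        return self

    def subset_otus(self, otu_ids: list[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(self.counts[:, idx], self.sample_ids, list(otu_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


def validate_table(table: OtuTable) -> None:
    counts = table.counts
    if counts.ndim != 2:
        raise ValidationError("count matrix must be 2-D")
    if not np.issubdtype(counts.dtype, np.integer):
        if np.issubdtype(counts.dtype, np.floating) and np.all(counts == np.floor(counts)):
            table.counts = counts.astype(np.int64)
        else:
            bad = np.argwhere(counts != np.floor(counts))
            i, j = bad[0] if len(bad) else (0, 0)
            raise ValidationError(
                f"non-integer count at sample {table.sample_ids[i]!r}, "
                f"OTU {table.otu_ids[j]!r}"
            )
    if (table.counts < 0).any():
        i, j = np.argwhere(table.counts < 0)[0]
        raise ValidationError(
            f"negative count at sample {table.sample_ids[i]!r}, OTU {table.otu_ids[j]!r}"
        )
    if len(set(table.sample_ids)) != len(table.sample_ids):
        raise ValidationError("duplicate sample identifiers")
    if len(set(table.otu_ids)) != len(table.otu_ids):
        raise ValidationError("duplicate OTU identifiers")
    if len(table.sample_ids) != table.counts.shape[0]:
        raise ValidationError("sample_ids length does not match count rows")
    if len(table.otu_ids) != table.counts.shape[1]:
        raise ValidationError("otu_ids length does not match count columns")
    if table.counts.shape[0] and (table.counts.sum(axis=1) == 0).any():
        empty = [s for s, t in zip(table.sample_ids, table.counts.sum(axis=1)) if t == 0]
        raise ValidationError(f"all-zero samples: {empty}")


@dataclass
class SampleMetadata:
    """Per-sample coordinates and environmental covariates.

    ``data`` holds one row per sample (index = sample id) with at least
    columns ``x`` and ``y`` (metres); ``blocks`` maps block names to the
    covariate columns they contain.
    """

    data: pd.DataFrame
    blocks: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("x", "y"):
            if col not in self.data.columns:
                raise ValidationError(f"metadata missing coordinate column {col!r}")
        for block, cols in self.blocks.items():
            missing = [c for c in cols if c not in self.data.columns]
            if missing:
                raise ValidationError(f"block {block!r} missing covariates {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def align_to(self, table: OtuTable) -> "SampleMetadata":
        """Reorder rows to the table's sample order; error on mismatch."""
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"metadata lacks samples: {sorted(missing)}")
        extra = set(self.sample_ids) - set(table.sample_ids)
        if extra:
            raise ValidationError(f"metadata has samples absent from table: {sorted(extra)}")
        return SampleMetadata(self.data.loc[table.sample_ids], dict(self.blocks))


# ---------------------------------------------------------------------------
# OTU table IO

def read_otu_table(path, samples_as_rows: bool | None = True) -> OtuTable:
    """Parse a tab-delimited OTU table.

    The first column holds sample identifiers and the header row OTU
    identifiers (``samples_as_rows=True``, the default). Pass ``False`` for
    the transposed layout, or ``None`` to auto-detect: the orientation with
    more columns than rows is assumed to put OTUs on columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        arr = df.to_numpy()
    except Exception as exc:  # pragma: no cover - pandas raises before this
        raise ValidationError(str(exc)) from exc
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError("OTU table contains non-numeric entries")
    if samples_as_rows is None:
        samples_as_rows = df.shape[1] >= df.shape[0]
    if not samples_as_rows:
        df = df.T
    return OtuTable(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))


def write_otu_table(table: OtuTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Tree IO

def read_tree(path) -> TreeNode:
    """Read a Newick phylogeny; missing branch lengths default to 0."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def check_tree_covers(tree: TreeNode, otu_ids: list[str]) -> None:
    """Error (listing ids) if any OTU lacks a tip on the tree."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(otu_ids) - tips)
    if missing:
        raise ValidationError(f"tree is missing tips for OTUs: {missing}")


def prune_tree(tree: TreeNode, otu_ids: list[str]) -> TreeNode:
    """Prune the tree to the given tips (lossless for shared tips)."""
    check_tree_covers(tree, otu_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tree.shear(otu_ids)


# ---------------------------------------------------------------------------
# Metadata IO

def read_metadata(path, blocks: dict[str, tuple[str, ...]] | None = None) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if blocks is None:
        blocks = {
            name: tuple(c for c in cols if c in df.columns)
            for name, cols in DEFAULT_BLOCKS.items()
        }
        blocks = {name: cols for name, cols in blocks.items() if cols}
    return SampleMetadata(df, blocks)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")
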