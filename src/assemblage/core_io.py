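"""Data model and file I/O for OTU count tables, sample metadata and trees.

The universal substrate is :class:`OtuTable`, an integer count matrix with
samples as rows and OTUs as columns.  Tables are exchanged as tab-separated
text (ids always travel with the counts, never positional indices);
phylogenies as newick.  Rarefaction is subsampling without replacement
(multivariate hypergeometric), with the random seed an explicit argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "rarefy",
    "to_relative",
]


@dataclass
class OtuTable:
    """Integer count matrix, rows = samples, columns = OTUs.

    Invariants (checked in ``__post_init__``): unique sample and OTU ids,
    matching dimensions, non-negative integral counts.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            dupes = sorted({o for o in self.otu_ids if self.otu_ids.count(o) > 1})
            raise ValueError(f"duplicate OTU ids: {dupes}")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.otu_ids)} OTUs)"
            )
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise ValueError(
                    f"non-integral count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def select(self, sample_ids=None, otu_ids=None) -> "OtuTable":
        """Restrict to given samples and/or OTUs, preserving the given order."""
        s_idx = (
            np.arange(self.n_samples)
            if sample_ids is None
            else np.array([self.sample_ids.index(s) for s in sample_ids], dtype=int)
        )
        o_idx = (
            np.arange(self.n_otus)
            if otu_ids is None
            else np.array([self.otu_ids.index(o) for o in otu_ids], dtype=int)
        )
        counts = self.counts[np.ix_(s_idx, o_idx)]
        return OtuTable(
            counts=counts,
            sample_ids=[self.sample_ids[i] for i in s_idx],
            otu_ids=[self.otu_ids[i] for i in o_idx],
            taxonomy=self.taxonomy,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def zero_otus(self) -> list[str]:
        """OTUs with zero total count (retained in the table, flagged here)."""
        tot = self.counts.sum(axis=0)
        return [o for o, t in zip(self.otu_ids, tot) if t == 0]


@dataclass
class SampleMetadata:
    """Per-sample treatment label, stressor dose (mg/kg dry soil) and replicate."""

    frame: pd.DataFrame  # columns: sample_id, treatment, dose, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "treatment", "dose", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate metadata sample ids: {sorted(set(dupes))}")
        if (self.frame["dose"] < 0).any():
            raise ValueError("negative dose in metadata")

    def validate_against(self, table: OtuTable) -> None:
        meta_ids = set(self.frame["sample_id"])
        table_ids = set(table.sample_ids)
        if not table_ids <= meta_ids:
            raise ValueError(f"samples without metadata: {sorted(table_ids - meta_ids)}")

    def treatments(self) -> list[str]:
        """Treatment labels in dose order (ties kept in file order)."""
        order = self.frame.drop_duplicates("treatment").sort_values(
            "dose", kind="stable"
        )
        return list(order["treatment"])

    def samples_of(self, treatment: str) -> list[str]:
        sel = self.frame[self.frame["treatment"] == treatment]
        if sel.empty:
            raise ValueError(f"unknown treatment: {treatment!r}")
        return list(sel["sample_id"])

    def dose_of(self, treatment: str) -> float:
        return float(self.frame.loc[self.frame["treatment"] == treatment, "dose"].iloc[0])


def read_otu_table(path, orientation: str = "samples-as-rows") -> OtuTable:
    """Read a tab-separated count table; first row and column are ids.

    A leading ``#OTU ID`` header cell (BIOM-style TSV) is accepted.  The
    returned table is normalised to samples-as-rows regardless of the file
    orientation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    if orientation == "otus-as-rows":
        df = df.T
    elif orientation != "samples-as-rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing/non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return OtuTable(
        counts=values, sample_ids=list(df.index), otu_ids=[str(c) for c in df.columns]
    )


def write_otu_table(table: OtuTable, path, orientation: str = "samples-as-rows") -> None:
    df = table.to_frame()
    if orientation == "otus-as-rows":
        df = df.T
        df.index.name = "#OTU ID"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "treatment": str})
    return SampleMetadata(frame=df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_tree(path) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths; tip labels are OTU ids."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    return tree


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Equivalent to drawing a multivariate hypergeometric sample from each
    row.  Samples whose total is below ``depth`` raise, listing offenders.
    OTU columns that end up all-zero are retained (see
    :meth:`OtuTable.zero_otus`) so id spaces stay aligned across treatments.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    totals = table.counts.sum(axis=1)
    short = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if short:
        raise ValueError(f"samples below rarefaction depth {depth}: {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return OtuTable(
        counts=out,
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        taxonomy=table.taxonomy,
    )


def to_relative(table: OtuTable) -> np.ndarray:
    """Row-normalised relative abundances; each row sums to 1.

    All-zero samples are rejected (a proportion is undefined for them).
    """
    totals = table.counts.sum(axis=1)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"all-zero samples have no relative abundances: {zero}")
    return table.counts / totals[:, None]


def warn_empty(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
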