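"""Levins' niche breadth per OTU and community-level mean niche width.

For OTU i with abundance proportions P_ij across r resource states,

    B_i = 1 / sum_j P_ij^2,

so B = 1 for a perfect specialist (all abundance in one state) and B = r
for a perfect generalist (uniform across states).  Resource states default
to individual samples; a treatment-level aggregation is available.  The
community niche width is the mean B over OTUs present in at least one
state of the chosen scope; absent OTUs are excluded (B is undefined for
them), never counted as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import OtuTable, SampleMetadata
from .partition import AbundanceClassification


def levins_breadth(abundances_over_states) -> float:
    """Levins' B for one OTU from its abundance across resource states."""
    a = np.asarray(abundances_over_states, dtype=float)
    if a.min() < 0:
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector; OTU should be excluded")
    p = a / total
    return float(1.0 / (p**2).sum())


@dataclass
class NicheResult:
    per_otu: pd.DataFrame  # otu_id (index), B, r
    r: int
    community_width: float


def _state_matrix(
    table: OtuTable, meta: SampleMetadata | None, states: str
) -> np.ndarray:
    """Rows = resource states, columns = OTUs."""
    if states == "samples":
        return table.counts.astype(float)
    if states == "treatments":
        if meta is None:
            raise ValueError("treatment states need sample metadata")
        present = set(table.sample_ids)
        rows = []
        for t in meta.treatments():
            idx = [table.sample_index(s) for s in meta.samples_of(t) if s in present]
            if idx:
                rows.append(table.counts[idx].sum(axis=0))
        return np.asarray(rows, dtype=float)
    raise ValueError(f"states must be 'samples' or 'treatments', got {states!r}")


def community_niche_width(
    table: OtuTable,
    cls: AbundanceClassification | None = None,
    which: str = "all",
    treatment: str | None = None,
    meta: SampleMetadata | None = None,
    states: str = "samples",
) -> NicheResult:
    """Mean Levins' B over the OTUs of one abundance class (or all OTUs).

    ``which``/``treatment`` select a subcommunity from a prior
    classification; with ``which="all"`` every OTU present in the scope is
    included.  States span the whole ``table`` given, so restrict the table
    first to compute a narrower-scope width.
    """
    mat = _state_matrix(table, meta, states)
    r = mat.shape[0]
    if r < 2:
        raise ValueError(f"need at least 2 resource states, got {r}")
    if which == "all":
        otus = list(table.otu_ids)
    else:
        if cls is None or treatment is None:
            raise ValueError("class-restricted width needs a classification and treatment")
        otus = [o for o in cls.otus_of(treatment, which) if o in set(table.otu_ids)]
    col = {o: j for j, o in enumerate(table.otu_ids)}
    rows = []
    for o in otus:
        vec = mat[:, col[o]]
        if vec.sum() > 0:
            rows.append({"otu_id": o, "B": levins_breadth(vec), "r": r})
    if not rows:
        warnings.warn(
            f"no present OTUs for class {which!r}; niche width is undefined",
            stacklevel=2,
        )
        return NicheResult(
            per_otu=pd.DataFrame(columns=["B", "r"]), r=r, community_width=float("nan")
        )
    per_otu = pd.DataFrame(rows).set_index("otu_id")
    return NicheResult(per_otu=per_otu, r=r, community_width=float(per_otu["B"].mean()))
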