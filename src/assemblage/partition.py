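"""Partition OTUs into abundant / moderate / rare subcommunities per treatment.

Cutoffs follow the convention for soil amplicon surveys: an OTU is
*abundant* in a treatment if its relative abundance reaches the abundant
cutoff (default 1%) in at least one sample of that treatment; *rare* if its
mean relative abundance across the treatment's samples is below the rare
cutoff (default 0.01%); *moderate* otherwise; *absent* if it has zero count
in every sample of the treatment.  Abundant takes precedence over rare when
both rules fire (possible for an OTU spiking in one replicate only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import OtuTable, SampleMetadata, to_relative

ABUNDANT_CUT = 0.01
RARE_CUT = 0.0001

CLASSES = ("abundant", "moderate", "rare", "absent")


@dataclass
class AbundanceClassification:
    """Per-(treatment, OTU) abundance class with the summary statistics used.

    ``frame`` columns: treatment, otu_id, class, mean_rel_abund, max_rel_abund.
    """

    frame: pd.DataFrame
    abundant_cut: float
    rare_cut: float

    def classes_of(self, treatment: str) -> pd.Series:
        sel = self.frame[self.frame["treatment"] == treatment]
        if sel.empty:
            raise ValueError(f"unknown treatment: {treatment!r}")
        return sel.set_index("otu_id")["class"]

    def otus_of(self, treatment: str, which: str) -> list[str]:
        if which not in CLASSES:
            raise ValueError(f"unknown class {which!r}; expected one of {CLASSES}")
        cls = self.classes_of(treatment)
        return list(cls.index[cls == which])


@dataclass
class TransitionRecord:
    otu_id: str
    ref_class: str
    target_class: str


def classify(
    table: OtuTable,
    meta: SampleMetadata,
    abundant_cut: float = ABUNDANT_CUT,
    rare_cut: float = RARE_CUT,
    pooled: bool = False,
) -> AbundanceClassification:
    """Classify every OTU in every treatment (or globally with ``pooled``).

    ``pooled=True`` treats the whole table as one group labelled ``"all"``
    (sensitivity-analysis mode); otherwise classification is per treatment.
    """
    if not (0 < rare_cut < abundant_cut < 1):
        raise ValueError(
            f"cutoffs must satisfy 0 < rare_cut < abundant_cut < 1, "
            f"got rare={rare_cut}, abundant={abundant_cut}"
        )
    meta.validate_against(table)
    rel = to_relative(table)
    groups = (
        [("all", list(table.sample_ids))]
        if pooled
        else [(t, [s for s in meta.samples_of(t) if s in set(table.sample_ids)])
              for t in meta.treatments()]
    )
    rows = []
    for treatment, samples in groups:
        if not samples:
            raise ValueError(f"treatment {treatment!r} has no samples in the table")
        idx = [table.sample_index(s) for s in samples]
        sub = rel[idx]
        mean_ra = sub.mean(axis=0)
        max_ra = sub.max(axis=0)
        labels = np.where(
            max_ra == 0,
            "absent",
            np.where(
                max_ra >= abundant_cut,
                "abundant",
                np.where(mean_ra < rare_cut, "rare", "moderate"),
            ),
        )
        for otu, lab, m, mx in zip(table.otu_ids, labels, mean_ra, max_ra):
            rows.append(
                {
                    "treatment": treatment,
                    "otu_id": otu,
                    "class": lab,
                    "mean_rel_abund": m,
                    "max_rel_abund": mx,
                }
            )
    return AbundanceClassification(
        frame=pd.DataFrame(rows), abundant_cut=abundant_cut, rare_cut=rare_cut
    )


def subcommunity(
    table: OtuTable,
    cls: AbundanceClassification,
    which: str,
    treatment: str,
    meta: SampleMetadata,
) -> OtuTable:
    """Restrict the table to one treatment's samples and one class's OTUs."""
    otus = cls.otus_of(treatment, which)
    samples = [s for s in meta.samples_of(treatment) if s in set(table.sample_ids)]
    if not otus:
        warnings.warn(
            f"empty {which} subcommunity in treatment {treatment!r}", stacklevel=2
        )
    return table.select(sample_ids=samples, otu_ids=otus)


def transitions(
    cls: AbundanceClassification, ref: str, target: str
) -> list[TransitionRecord]:
    """Track per-OTU class changes between two treatments.

    One record per OTU present (non-absent) in either treatment; supports
    queries such as "rare in the reference and abundant under stress".
    """
    ref_cls = cls.classes_of(ref)
    tgt_cls = cls.classes_of(target)
    records = []
    for otu in ref_cls.index:
        a, b = ref_cls[otu], tgt_cls[otu]
        if a == "absent" and b == "absent":
            continue
        records.append(TransitionRecord(otu_id=otu, ref_class=a, target_class=b))
    return records


def transition_counts(records: list[TransitionRecord]) -> pd.DataFrame:
    """Contingency table of transitions: rows = reference class, cols = target."""
    df = pd.DataFrame(
        [(r.ref_class, r.target_class) for r in records],
        columns=["ref_class", "target_class"],
    )
    return (
        df.groupby(["ref_class", "target_class"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=CLASSES, columns=CLASSES, fill_value=0)
    )
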