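"""Alpha diversity, Bray-Curtis dissimilarity and a Shannon-based
resistance index.

Shannon entropy is reported in nats; Simpson is the Gini-Simpson form
1 - sum(p^2).  Resistance follows the bounded disturbance-response index

    RS = 1 - 2|D0| / (C0 + |D0|),   D0 = C0 - P0,

where C0 is the control-mean Shannon and P0 the perturbed value: RS = 1
when the perturbed community matches the control, 0 at total loss
(P0 = 0), and strictly decreasing in |D0|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .core_io import OtuTable, SampleMetadata


def shannon(counts) -> float:
    """Shannon-Wiener index -sum(p ln p) over positive entries, in nats."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("Shannon undefined for an all-zero vector")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum(p^2)."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("Simpson undefined for an all-zero vector")
    p = c / c.sum()
    return float(1.0 - (p**2).sum())


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample Shannon (nats), Gini-Simpson and richness."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        rows.append(
            {
                "sample_id": sid,
                "shannon": shannon(c),
                "simpson": simpson(c),
                "richness": int((c > 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: OtuTable) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix, BC = sum|x-y| / sum(x+y).

    A pair of all-zero samples has undefined dissimilarity and is reported
    as NaN rather than raising.
    """
    if table.n_samples < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    counts = table.counts.astype(float)
    with np.errstate(invalid="ignore"):
        mat = squareform(pdist(counts, metric="braycurtis"))
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        mat[np.ix_(zero, zero)] = np.nan
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class ResistanceResult:
    C0: float  # control-mean Shannon, nats
    P0: float  # perturbed Shannon, nats
    D0: float  # C0 - P0
    RS: float  # resistance index in (-1, 1]


def resistance(control_shannons, perturbed_shannon: float) -> ResistanceResult:
    """Resistance of a diversity metric relative to the unperturbed control."""
    control = np.asarray(control_shannons, dtype=float)
    if control.size == 0:
        raise ValueError("control vector is empty")
    c0 = float(control.mean())
    if c0 <= 0:
        raise ValueError(f"control-mean Shannon must be positive, got {c0}")
    p0 = float(perturbed_shannon)
    d0 = c0 - p0
    rs = 1.0 - 2.0 * abs(d0) / (c0 + abs(d0))
    return ResistanceResult(C0=c0, P0=p0, D0=d0, RS=rs)


def treatment_resistance(
    table: OtuTable, meta: SampleMetadata, control: str = "Control"
) -> pd.DataFrame:
    """Per-replicate resistance against the control-treatment mean Shannon.

    Returns one row per non-control sample (treatment, sample_id, RS ...);
    treatment-level resistance is the mean of its replicate values.
    """
    alpha = alpha_diversity(table)
    control_samples = [
        s for s in meta.samples_of(control) if s in set(table.sample_ids)
    ]
    if not control_samples:
        raise ValueError(f"no control samples ({control!r}) in the table")
    c_vals = alpha.loc[control_samples, "shannon"].to_numpy()
    rows = []
    for treatment in meta.treatments():
        if treatment == control:
            continue
        for sid in meta.samples_of(treatment):
            if sid not in alpha.index:
                continue
            res = resistance(c_vals, alpha.loc[sid, "shannon"])
            rows.append(
                {
                    "treatment": treatment,
                    "sample_id": sid,
                    "C0": res.C0,
                    "P0": res.P0,
                    "D0": res.D0,
                    "RS": res.RS,
                }
            )
    return pd.DataFrame(rows)
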