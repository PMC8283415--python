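"""Sloan neutral community model: occurrence frequency vs mean abundance.

Under neutral drift with immigration probability m into local communities
of size N, the stationary relative abundance of a taxon with metacommunity
mean relative abundance p follows Beta(N*m*p, N*m*(1-p)).  The predicted
occurrence frequency across samples is the probability this abundance
exceeds a detection limit d (default one read, d = 1/N):

    f_hat(p) = 1 - BetaCDF(d; N*m*p, N*m*(1-p))

The single free parameter m is fitted by bounded least squares of observed
frequencies against the prediction; N is fixed to the mean sample depth
(the rarefaction depth for a rarefied table) rather than co-estimated.
R^2 = 1 - SSE/SST may be negative for strongly anti-neutral data and is
reported unclamped.  95% Wilson binomial bounds around the predicted
frequency at n = number of samples partition OTUs into those occurring
more often (above), consistently (neutral), or less often (below) than the
neutral expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import OtuTable, to_relative


def predict_frequency(p, m: float, N: float, d: float) -> np.ndarray:
    """Predicted occurrence frequency for mean relative abundance(s) p."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("mean relative abundance must lie in (0, 1)")
    if not (0 < m <= 1):
        raise ValueError(f"immigration probability m must be in (0, 1], got {m}")
    if N < 1:
        raise ValueError(f"community size N must be >= 1, got {N}")
    if not (0 < d < 1):
        raise ValueError(f"detection limit d must be in (0, 1), got {d}")
    return stats.beta.sf(d, N * m * p, N * m * (1.0 - p))


@dataclass
class NcmFit:
    m: float
    N: float
    Nm: float
    d: float
    r2: float
    n_samples: int
    per_otu: pd.DataFrame  # otu_id (index), p, f_obs, f_pred, ci_lo, ci_hi, partition

    @property
    def partition_fractions(self) -> pd.Series:
        frac = self.per_otu["partition"].value_counts(normalize=True)
        return frac.reindex(["above", "neutral", "below"], fill_value=0.0)

    def summary(self) -> dict:
        return {
            "m": self.m,
            "N": self.N,
            "Nm": self.Nm,
            "d": self.d,
            "R2": self.r2,
            "n_samples": self.n_samples,
            "n_otus": int(len(self.per_otu)),
        }


def _wilson_bounds(f_pred: np.ndarray, n: int, alpha: float = 0.05) -> tuple:
    """Wilson score interval for a binomial proportion f_pred at n trials."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    denom = 1.0 + z**2 / n
    centre = (f_pred + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(f_pred * (1 - f_pred) / n + z**2 / (4 * n**2))
    return np.clip(centre - half, 0.0, 1.0), np.clip(centre + half, 0.0, 1.0)


def fit_occurrence(
    p,
    f_obs,
    n_samples: int,
    N: float,
    d: float | None = None,
    otu_ids: list[str] | None = None,
    m_bounds: tuple = (1e-6, 1.0),
) -> NcmFit:
    """Fit m by least squares given mean abundances and occurrence frequencies.

    The frequency-level core of :func:`fit_ncm`, exposed so the fit can be
    exercised on constructed (p, f_obs) data independent of any table.
    """
    p = np.asarray(p, dtype=float)
    f_obs = np.asarray(f_obs, dtype=float)
    if d is None:
        d = 1.0 / N
    if otu_ids is None:
        otu_ids = [f"OTU{i + 1}" for i in range(p.size)]
    p = np.clip(p, 1e-12, 1 - 1e-12)
    n_informative = int(((f_obs > 0) & (f_obs < 1)).sum())
    if n_informative < 10:
        raise ValueError(
            f"degenerate data: only {n_informative} OTUs with intermediate "
            "occurrence frequency; the neutral fit is unidentifiable"
        )

    def sse(m: float) -> float:
        return float(((f_obs - predict_frequency(p, m, N, d)) ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=m_bounds, method="bounded",
                                   options={"xatol": 1e-10})
    m_hat = float(res.x)
    f_pred = predict_frequency(p, m_hat, N, d)
    sst = float(((f_obs - f_obs.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")
    lo, hi = _wilson_bounds(f_pred, n_samples)
    part = np.where(f_obs > hi, "above", np.where(f_obs < lo, "below", "neutral"))
    per_otu = pd.DataFrame(
        {
            "p": p,
            "f_obs": f_obs,
            "f_pred": f_pred,
            "ci_lo": lo,
            "ci_hi": hi,
            "partition": part,
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )
    return NcmFit(
        m=m_hat, N=N, Nm=N * m_hat, d=d, r2=r2,
        n_samples=n_samples, per_otu=per_otu,
    )


def fit_ncm(
    table: OtuTable,
    N: float | None = None,
    d: float | None = None,
    m_bounds: tuple = (1e-6, 1.0),
) -> NcmFit:
    """Fit the neutral model to a count table.

    Occurrence frequency and mean relative abundance are computed over the
    samples of the table passed in (fit one treatment by restricting the
    table first).  OTUs absent from every sample are dropped.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples to fit occurrence frequencies")
    rel = to_relative(table)
    present = table.counts.sum(axis=0) > 0
    p = rel.mean(axis=0)[present]
    f_obs = (table.counts > 0).mean(axis=0)[present]
    otu_ids = [o for o, keep in zip(table.otu_ids, present) if keep]
    if N is None:
        N = float(table.counts.sum(axis=1).mean())
    return fit_occurrence(
        p, f_obs, table.n_samples, N, d=d, otu_ids=otu_ids, m_bounds=m_bounds
    )
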