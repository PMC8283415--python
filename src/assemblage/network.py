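"""Spearman co-occurrence networks with RMT-guided threshold selection.

Edges are signed Spearman rank correlations whose magnitude clears a
cutoff.  The cutoff can be chosen by random-matrix theory: as the
threshold rises, the nearest-neighbour spacing distribution (NNSD) of the
unfolded eigenvalue spectrum of the thresholded correlation matrix
transitions from Wigner-Dyson (level repulsion, correlated noise) to
Poisson (uncorrelated, modular signal); the smallest threshold whose NNSD
is consistent with Poisson is used.  Node topology (degree, raw and
normalised betweenness, local clustering) and a log-log power-law fit of
the degree distribution characterise the resulting graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import OtuTable
from .partition import AbundanceClassification


def spearman_matrix(
    table: OtuTable, prevalence_min: float = 1 / 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (ties mid-ranked) and p-values over samples.

    OTUs present in fewer than ``prevalence_min`` of samples are removed
    first (the "majority rule" prevalence filter).  Constant OTU vectors
    have undefined correlation; their pairs are reported as NaN.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples for rank correlations")
    keep = (table.counts > 0).mean(axis=0) >= prevalence_min
    otus = [o for o, k in zip(table.otu_ids, keep) if k]
    sub = table.counts[:, keep].astype(float)
    if len(otus) < 2:
        eye = np.ones((len(otus), len(otus)))
        return (
            pd.DataFrame(eye, index=otus, columns=otus),
            pd.DataFrame(np.zeros_like(eye), index=otus, columns=otus),
        )
    # Spearman = Pearson on mid-ranks; computed directly so constant
    # columns degrade to NaN pairs instead of tripping scipy edge cases
    ranks = np.apply_along_axis(stats.rankdata, 0, sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    n = table.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
        pval = 2.0 * stats.t.sf(np.abs(t_stat), df=n - 2)
    const = sub.std(axis=0) == 0
    if const.any():
        rho[const, :] = np.nan
        rho[:, const] = np.nan
        pval[const, :] = np.nan
        pval[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    return (
        pd.DataFrame(rho, index=otus, columns=otus),
        pd.DataFrame(pval, index=otus, columns=otus),
    )


def _unfold_spectrum(eigs: np.ndarray, poly_degree: int = 5) -> np.ndarray:
    """Unfold eigenvalues: map through a smoothed cumulative spectral function
    so the mean level spacing becomes 1."""
    eigs = np.sort(eigs)
    cdf = np.arange(1, eigs.size + 1, dtype=float)
    # distinct abscissae for a stable polynomial fit
    uniq, idx = np.unique(np.round(eigs, 10), return_index=True)
    if uniq.size <= poly_degree + 1:
        return np.diff(cdf)
    coef = np.polynomial.polynomial.polyfit(eigs[idx], cdf[idx], poly_degree)
    smooth = np.polynomial.polynomial.polyval(eigs, coef)
    return np.diff(np.sort(smooth))


def _nnsd_poisson_pvalue(spacings: np.ndarray, n_bins: int = 20,
                         s_max: float = 3.0) -> float:
    """Chi-square goodness of fit of spacings against the Poisson NNSD e^-s."""
    spacings = spacings[np.isfinite(spacings)]
    spacings = spacings[spacings >= 0]
    if spacings.size < n_bins:
        return 0.0
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs, _ = np.histogram(np.clip(spacings, 0, s_max - 1e-12), bins=edges)
    expected = spacings.size * (np.exp(-edges[:-1]) - np.exp(-edges[1:]))
    expected[-1] += spacings.size * np.exp(-edges[-1])  # tail mass
    mask = expected > 0
    chi2 = float(((obs[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    dof = max(int(mask.sum()) - 1, 1)
    return float(stats.chi2.sf(chi2, dof))


def rmt_threshold(
    rho: pd.DataFrame | np.ndarray,
    t_min: float = 0.30,
    t_max: float = 0.99,
    step: float = 0.01,
    alpha: float = 0.05,
    fallback: float = 0.8,
) -> tuple[float, bool]:
    """Scan thresholds; return the smallest whose NNSD looks Poisson.

    Returns ``(threshold, used_fallback)``.  If no scanned threshold
    qualifies, the fallback cutoff is returned with a warning.
    """
    mat = np.asarray(rho, dtype=float).copy()
    if mat.shape[0] < 50:
        warnings.warn(
            "correlation matrix smaller than 50x50; the eigenvalue spectrum "
            "is too sparse for a reliable RMT scan",
            stacklevel=2,
        )
    mat[~np.isfinite(mat)] = 0.0
    thresholds = np.arange(t_min, t_max + step / 2, step)
    for t in thresholds:
        m = np.where(np.abs(mat) >= t, mat, 0.0)
        np.fill_diagonal(m, 1.0)
        eigs = np.linalg.eigvalsh(m)
        spacings = _unfold_spectrum(eigs)
        if _nnsd_poisson_pvalue(spacings) > alpha:
            return float(round(t, 10)), False
    warnings.warn(
        f"no threshold in [{t_min}, {t_max}] gave a Poisson NNSD; "
        f"falling back to |rho| >= {fallback}",
        stacklevel=2,
    )
    return fallback, True


@dataclass
class CoocNetwork:
    """Thresholded signed Spearman graph with abundance-class annotation."""

    graph: nx.Graph
    threshold: float
    node_classes: dict[str, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(u, v, d["rho"]) for u, v, d in self.graph.edges(data=True)],
            columns=["source", "target", "rho"],
        )


def build_network(
    rho: pd.DataFrame,
    threshold: float,
    cls: AbundanceClassification | None = None,
    treatment: str | None = None,
    mode: str = "full",
) -> CoocNetwork:
    """Build the co-occurrence graph from a correlation matrix.

    ``mode="abundant-rare"`` keeps only edges linking an abundant OTU to a
    rare one (the subcommunity-interaction networks); it requires a
    classification and treatment.  Nodes without edges are dropped.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    node_classes: dict[str, str] = {}
    if cls is not None and treatment is not None:
        node_classes = cls.classes_of(treatment).to_dict()
    g = nx.Graph()
    otus = list(rho.index)
    mat = rho.to_numpy()
    for i in range(len(otus)):
        for j in range(i + 1, len(otus)):
            r = mat[i, j]
            if not np.isfinite(r) or abs(r) < threshold:
                continue
            if mode == "abundant-rare":
                pair = {node_classes.get(otus[i]), node_classes.get(otus[j])}
                if pair != {"abundant", "rare"}:
                    continue
            g.add_edge(otus[i], otus[j], rho=float(r))
    if g.number_of_edges() == 0:
        warnings.warn("network is empty at this threshold", stacklevel=2)
    for node in g.nodes:
        g.nodes[node]["abundance_class"] = node_classes.get(node, "unclassified")
    return CoocNetwork(graph=g, threshold=threshold, node_classes=node_classes)


def node_topology(net: CoocNetwork) -> pd.DataFrame:
    """Degree, betweenness (raw and normalised) and clustering per node."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = dict(g.degree())
    btw_raw = nx.betweenness_centrality(g, normalized=False)
    btw_norm = nx.betweenness_centrality(g, normalized=True)
    clust = nx.clustering(g)
    return pd.DataFrame(
        {
            "class": {n: g.nodes[n].get("abundance_class", "unclassified")
                      for n in g.nodes},
            "degree": deg,
            "betweenness": btw_raw,
            "betweenness_norm": btw_norm,
            "clustering": clust,
        }
    ).rename_axis("otu_id")


def power_law_fit(degree_sequence) -> float:
    """R^2 of the least-squares log(frequency) vs log(degree) line.

    Returns NaN (with a warning) when fewer than 4 distinct positive
    degrees exist - the scale-free fit is then meaningless.
    """
    deg = np.asarray(degree_sequence, dtype=float)
    deg = deg[deg > 0]
    values, counts = np.unique(deg, return_counts=True)
    if values.size < 4:
        warnings.warn(
            f"only {values.size} distinct degree values; power-law fit skipped",
            stacklevel=2,
        )
        return float("nan")
    x = np.log(values)
    y = np.log(counts.astype(float))
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def to_graphml(net: CoocNetwork, path) -> None:
    nx.write_graphml(net.graph, str(path))
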