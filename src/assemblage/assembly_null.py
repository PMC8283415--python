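"""Phylogenetic and taxonomic null models for community assembly.

Two pairwise turnover statistics are standardised against randomisations:

* beta-MNTD / beta-NTI - the abundance-weighted between-community mean
  nearest taxon distance, standardised against a null that shuffles tip
  labels across the whole tree (the regional pool being every OTU in the
  scope).  |betaNTI| > 2 signals deterministic turnover: betaNTI < -2
  homogeneous selection (less phylogenetic turnover than expected),
  betaNTI > 2 variable selection.

* probabilistic Raup-Crick on Bray-Curtis (RC_Bray) - the observed
  Bray-Curtis dissimilarity ranked within null community pairs that
  preserve each sample's richness and total abundance, species drawn with
  probability proportional to occurrence frequency and individuals
  proportional to regional mean relative abundance.  RC is rescaled to
  [-1, 1]; |RC| > 0.95 at |betaNTI| < 2 separates dispersal limitation
  (RC > 0.95) from homogenizing dispersal (RC < -0.95), and |RC| < 0.95
  leaves the pair "undominated".

The null shuffles only identities: each community's richness and abundance
vector are untouched.  All randomness flows from an explicit seed; equal
seeds give bit-identical matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .core_io import OtuTable, SampleMetadata, to_relative

PROCESSES = (
    "homogeneous_selection",
    "variable_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "undominated",
)


def patristic_distances(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Dense tip-to-tip patristic distance matrix via one postorder pass.

    For every internal node the tips of its child subtrees are merged;
    cross-subtree distances are the outer sums of tip-to-node path lengths.
    O(n^2) time, no quadratic tree re-traversals.
    """
    labels: list[str] = []
    index: dict[int, int] = {}
    for leaf in tree.leaf_node_iter():
        index[id(leaf)] = len(labels)
        labels.append(leaf.taxon.label)
    n = len(labels)
    D = np.zeros((n, n))
    store: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            store[id(node)] = (np.array([index[id(node)]]), np.zeros(1))
            continue
        parts = []
        for child in node.child_nodes():
            idxs, dists = store.pop(id(child))
            bl = child.edge.length if child.edge.length is not None else 0.0
            parts.append((idxs, dists + bl))
        for a in range(len(parts)):
            for b in range(a + 1, len(parts)):
                ia, da = parts[a]
                ib, db = parts[b]
                block = da[:, None] + db[None, :]
                D[np.ix_(ia, ib)] = block
                D[np.ix_(ib, ia)] = block.T
        store[id(node)] = (
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
        )
    return D, labels


def _align_distance(table: OtuTable, tree: dendropy.Tree) -> np.ndarray:
    D, labels = patristic_distances(tree)
    pos = {lab: i for i, lab in enumerate(labels)}
    missing = [o for o in table.otu_ids if o not in pos]
    if missing:
        raise ValueError(f"OTUs missing from the tree: {missing[:10]}")
    order = np.array([pos[o] for o in table.otu_ids])
    return D[np.ix_(order, order)]


def beta_mntd(
    comm_a, comm_b, tree: dendropy.Tree, otu_ids: list[str]
) -> float:
    """Abundance-weighted beta-MNTD between two communities.

    ``comm_a``/``comm_b`` are abundance vectors over ``otu_ids``; every OTU
    present in either community must be a tip of ``tree``.
    """
    a = np.asarray(comm_a, dtype=float)
    b = np.asarray(comm_b, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both communities must be non-empty")
    table = OtuTable(
        counts=np.zeros((2, len(otu_ids)), dtype=int),
        sample_ids=["a", "b"],
        otu_ids=list(otu_ids),
    )
    D = _align_distance(table, tree)
    return float(_beta_mntd_matrix(np.vstack([a, b]), D)[0, 1])


def _beta_mntd_matrix(abund: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Pairwise beta-MNTD for all sample pairs given a tip-distance matrix."""
    rel = abund / abund.sum(axis=1, keepdims=True)
    n_samples = abund.shape[0]
    # minvec[l, i] = distance from taxon i to its nearest taxon present in l
    minvec = np.empty((n_samples, abund.shape[1]))
    for k in range(n_samples):
        cols = np.flatnonzero(abund[k] > 0)
        minvec[k] = D[:, cols].min(axis=1)
    out = np.zeros((n_samples, n_samples))
    for k in range(n_samples):
        for l in range(k + 1, n_samples):
            v = 0.5 * (rel[k] @ minvec[l] + rel[l] @ minvec[k])
            out[k, l] = out[l, k] = v
    return out


def bnti(
    table: OtuTable,
    tree: dendropy.Tree,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """beta-NTI matrix: observed beta-MNTD standardised against tip shuffles.

    The null permutes tip identities jointly on rows and columns of the
    precomputed distance matrix; communities keep their abundances.  Pairs
    whose null distribution has zero spread (e.g. a star tree with equal
    branch lengths) are reported as NaN with a warning.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    D = _align_distance(table, tree)
    abund = table.counts.astype(float)
    if np.any(abund.sum(axis=1) <= 0):
        raise ValueError("all samples must be non-empty")
    obs = _beta_mntd_matrix(abund, D)
    rng = np.random.default_rng(seed)
    n_otus = table.n_otus
    rel = abund / abund.sum(axis=1, keepdims=True)
    present = [np.flatnonzero(abund[k] > 0) for k in range(table.n_samples)]
    null_sum = np.zeros_like(obs)
    null_sumsq = np.zeros_like(obs)
    S = table.n_samples
    for _ in range(n_null):
        perm = rng.permutation(n_otus)
        minvec = np.empty((S, n_otus))
        for k in range(S):
            # nearest permuted-tip distance, re-indexed back to OTU order
            minvec[k] = D[:, perm[present[k]]].min(axis=1)[perm]
        bm = np.zeros((S, S))
        for k in range(S):
            for l in range(k + 1, S):
                v = 0.5 * (rel[k] @ minvec[l] + rel[l] @ minvec[k])
                bm[k, l] = bm[l, k] = v
        null_sum += bm
        null_sumsq += bm**2
    mean = null_sum / n_null
    var = null_sumsq / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate = (sd <= 1e-12) & ~np.eye(S, dtype=bool)
    if degenerate.any():
        warnings.warn(
            "null beta-MNTD has zero spread for some pairs; betaNTI undefined "
            "(reported as NaN)",
            stacklevel=2,
        )
        z[degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


def _null_community(rng, richness: int, total: int, freq_p: np.ndarray,
                    abund_p: np.ndarray) -> np.ndarray:
    """One Raup-Crick null community: fixed richness and total abundance."""
    n_otus = freq_p.size
    chosen = rng.choice(n_otus, size=richness, replace=False, p=freq_p)
    counts = np.zeros(n_otus, dtype=np.int64)
    counts[chosen] = 1  # each chosen species is observed at least once
    remaining = total - richness
    if remaining > 0:
        w = abund_p[chosen]
        counts[chosen] += rng.multinomial(remaining, w / w.sum())
    return counts


def _bray_curtis_pair(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    return float(np.abs(x - y).sum() / denom) if denom else float("nan")


def raup_crick_bray(
    table: OtuTable,
    n_null: int = 999,
    seed: int = 0,
    pool_freq=None,
    pool_abund=None,
) -> pd.DataFrame:
    """Probabilistic Raup-Crick on Bray-Curtis, rescaled to [-1, 1].

    For each sample pair, ``n_null`` null pairs are generated: species
    membership drawn (without replacement, preserving observed richness)
    with probability proportional to occurrence frequency across the
    scope, and individuals assigned (preserving total abundance) with
    probability proportional to regional mean relative abundance.
    RC = 2 * [(#null BC < observed BC) + 0.5 * #ties] / n_null - 1.

    By default the regional pool (occurrence frequencies and mean relative
    abundances) is estimated from ``table`` itself; ``pool_freq`` /
    ``pool_abund`` (vectors over the table's OTUs) pin it externally, e.g.
    to the whole community when a subcommunity is analysed.
    """
    if table.n_samples < 2:
        raise ValueError("Raup-Crick needs at least 2 samples")
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    counts = table.counts
    present = counts > 0
    freq = (
        np.asarray(pool_freq, dtype=float)
        if pool_freq is not None
        else present.mean(axis=0).astype(float)
    )
    pool = freq > 0
    if not pool.any():
        raise ValueError("empty table")
    if pool_abund is not None:
        regional = np.asarray(pool_abund, dtype=float)
    else:
        rel = to_relative(table)
        regional = rel.mean(axis=0)
    freq_p = freq[pool] / freq[pool].sum()
    abund_p = regional[pool] / regional[pool].sum()
    S = table.n_samples
    richness = present.sum(axis=1)
    totals = counts.sum(axis=1)
    rng = np.random.default_rng(seed)
    rc = np.zeros((S, S))
    sub = counts[:, pool].astype(np.int64)
    for k in range(S):
        for l in range(k + 1, S):
            obs = _bray_curtis_pair(sub[k], sub[l])
            below = ties = 0
            for _ in range(n_null):
                nk = _null_community(rng, int(richness[k]), int(totals[k]), freq_p, abund_p)
                nl = _null_community(rng, int(richness[l]), int(totals[l]), freq_p, abund_p)
                bc = _bray_curtis_pair(nk, nl)
                if abs(bc - obs) <= 1e-12:
                    ties += 1
                elif bc < obs:
                    below += 1
            val = 2.0 * (below + 0.5 * ties) / n_null - 1.0
            rc[k, l] = rc[l, k] = val
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


def classify_process(bnti_value: float, rc_value: float) -> str:
    """Map a (betaNTI, RC_Bray) pair to its assembly-process label.

    Boundary values are resolved deterministically: |betaNTI| = 2 counts as
    selection, |RC| = 0.95 as the dispersal class.
    """
    if not (np.isfinite(bnti_value) and np.isfinite(rc_value)):
        raise ValueError("betaNTI and RC must both be finite")
    if bnti_value <= -2:
        return "homogeneous_selection"
    if bnti_value >= 2:
        return "variable_selection"
    if rc_value <= -0.95:
        return "homogenizing_dispersal"
    if rc_value >= 0.95:
        return "dispersal_limitation"
    return "undominated"


@dataclass
class AssemblyResult:
    """Pairwise turnover statistics with per-pair process labels.

    ``pairs`` is long-format: sample_a, sample_b, group, betaMNTD, betaNTI,
    RC, process.  ``n_null`` and ``seed`` record the null configuration.
    """

    pairs: pd.DataFrame
    n_null: int
    seed: int

    def fractions(self) -> pd.DataFrame:
        """Per-group fraction of pairs assigned to each process (rows sum to 1).

        Pairs whose betaNTI or RC is undefined (degenerate nulls) are
        excluded from the denominator; a group with no classifiable pair is
        dropped with a warning.
        """
        rows = []
        for group, sel in self.pairs.groupby("group"):
            counts = sel.loc[sel["process"] != "undefined", "process"].value_counts()
            total = counts.sum()
            if total == 0:
                warnings.warn(f"group {group!r} has no classified pairs", stacklevel=2)
                continue
            if total < len(sel):
                warnings.warn(
                    f"group {group!r}: {len(sel) - total} pair(s) with undefined "
                    "null statistics excluded",
                    stacklevel=2,
                )
            frac = counts.reindex(PROCESSES, fill_value=0) / total
            rows.append(pd.Series(frac, name=group))
        return pd.DataFrame(rows).rename_axis("group")


def _pair_groups(
    meta: SampleMetadata, sample_ids: list[str], scope: str, control: str | None
) -> list[tuple[str, str, str]]:
    """Enumerate (sample_a, sample_b, group) under the pair-scope policy."""
    by_treatment = {
        t: [s for s in meta.samples_of(t) if s in set(sample_ids)]
        for t in meta.treatments()
    }
    pairs = []
    if scope == "all":
        for i, a in enumerate(sample_ids):
            for b in sample_ids[i + 1:]:
                pairs.append((a, b, "all"))
        return pairs
    for t, samples in by_treatment.items():
        for i, a in enumerate(samples):
            for b in samples[i + 1:]:
                pairs.append((a, b, t))
        if scope == "within+control" and control is not None and t != control:
            for a in by_treatment.get(control, []):
                for b in samples:
                    pairs.append((a, b, t))
    return pairs


def assembly_processes(
    table: OtuTable,
    tree: dendropy.Tree,
    meta: SampleMetadata,
    n_null: int = 999,
    seed: int = 0,
    scope: str = "within+control",
    control: str | None = "Control",
) -> AssemblyResult:
    """Full null-model analysis: betaNTI + RC_Bray + process per sample pair.

    ``scope`` selects which pairs are classified and how they are grouped:
    ``"within"`` (within-treatment pairs only), ``"within+control"``
    (default; adds control-vs-treatment pairs to each treatment's group) or
    ``"all"`` (every pair, one group).
    """
    z = bnti(table, tree, n_null=n_null, seed=seed)
    rc = raup_crick_bray(table, n_null=n_null, seed=seed + 1)
    bm = pd.DataFrame(
        _beta_mntd_matrix(table.counts.astype(float), _align_distance(table, tree)),
        index=table.sample_ids,
        columns=table.sample_ids,
    )
    rows = []
    for a, b, group in _pair_groups(meta, table.sample_ids, scope, control):
        zval, rval = z.loc[a, b], rc.loc[a, b]
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "group": group,
                "betaMNTD": bm.loc[a, b],
                "betaNTI": zval,
                "RC": rval,
                "process": classify_process(zval, rval)
                if np.isfinite(zval) and np.isfinite(rval)
                else "undefined",
            }
        )
    return AssemblyResult(pairs=pd.DataFrame(rows), n_null=n_null, seed=seed)
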