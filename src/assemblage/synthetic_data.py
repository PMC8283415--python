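"""Synthetic OTU tables, phylogenies and traits with known ground truth.

Three generators cover the test surface of the whole pipeline:

* :func:`simulate_phylogeny` - a Yule (pure-birth) tree scaled to unit
  depth, with a per-tip environmental optimum evolved by Brownian motion,
  so that selection acting on the trait is phylogenetically conserved and
  detectable by phylogenetic null models.

* :func:`simulate_neutral` - independent local communities assembled by a
  death-replacement (Moran) process with immigration probability ``m``
  from a fixed lognormal metacommunity; the ground-truth generator for
  neutral-model fitting and null-model calibration.

* :func:`simulate_gradient` - multinomial sampling with per-treatment
  selection weights ``w_i \\propto meta_i * exp(s * dose_scaled * trait_i)``,
  emulating dose-dependent enrichment of a degrader clade along a
  stressor gradient.

Neutral and gradient generators share the metacommunity, so contrasts
between them isolate the selection term.  Everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .core_io import OtuTable, SampleMetadata, write_metadata, write_otu_table

import pandas as pd

# Default study design: 5 stressor levels (mg/kg dry soil) x 6 replicates,
# thousands of OTUs rarefied to a common depth.
DEFAULT_TREATMENTS = [
    ("Control", 0.0),
    ("PYR1", 1.0),
    ("PYR10", 10.0),
    ("PYR100", 100.0),
    ("PYR500", 500.0),
]


@dataclass
class SimulationConfig:
    """Knobs of the community simulators.

    ``m`` is the neutral immigration probability; ``selection_strength``
    scales the dose-by-trait selection exponent in gradient mode;
    ``degrader_fraction`` marks the top-trait OTUs as the positively
    responding clade in the ground truth.
    """

    n_otus: int = 2000
    n_samples_per_treatment: int = 6
    treatments: list = field(default_factory=lambda: list(DEFAULT_TREATMENTS))
    depth: int = 39134
    metacommunity_mu: float = 0.0
    metacommunity_sigma: float = 2.0
    m: float = 0.65
    selection_strength: float = 3.0
    degrader_fraction: float = 0.1
    trait_model_var: float = 1.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_treatment * len(self.treatments)


def _otu_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"OTU{i + 1:0{width}d}" for i in range(n)]


def metacommunity(config: SimulationConfig) -> np.ndarray:
    """Lognormal metacommunity relative abundances (few dominants, long
    rare tail), deterministic under the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    raw = rng.lognormal(config.metacommunity_mu, config.metacommunity_sigma,
                        config.n_otus)
    return raw / raw.sum()


def simulate_phylogeny(
    n_otus: int, seed: int, trait_var: float = 1.0
) -> tuple[dendropy.Tree, pd.Series]:
    """Yule tree scaled to unit depth + Brownian environmental optima.

    Returns the tree (tip labels ``OTU0001``...) and a per-tip trait
    Series.  Trait variance accumulates proportionally to branch length,
    so closely related tips carry similar optima.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    labels = _otu_ids(n_otus)
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_otus,
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    tree.is_rooted = True
    tree.seed_node.edge.length = None  # no stem below the root
    rng_edge = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    # the simulator stops exactly at the n-th birth, leaving the newest
    # cherry at zero patristic distance; run the clock to the next (never
    # realised) speciation so every pendant edge is positive and the tree
    # stays ultrametric
    dt = rng_edge.exponential(1.0 / n_otus)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
    # scale so the deepest tip sits at distance 1 from the root
    max_depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    if max_depth > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= max_depth
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    trait: dict = {}
    for node in tree.preorder_node_iter():
        parent_val = 0.0 if node.parent_node is None else trait[id(node.parent_node)]
        bl = node.edge.length if node.edge.length is not None else 0.0
        trait[id(node)] = parent_val + rng.normal(0.0, np.sqrt(trait_var * bl)) if bl > 0 else parent_val
    tip_traits = pd.Series(
        {leaf.taxon.label: trait[id(leaf)] for leaf in tree.leaf_node_iter()}
    ).reindex(labels)
    return tree, tip_traits


def _metadata_frame(config: SimulationConfig) -> SampleMetadata:
    rows = []
    for label, dose in config.treatments:
        for rep in range(1, config.n_samples_per_treatment + 1):
            rows.append(
                {
                    "sample_id": f"{label}_r{rep}",
                    "treatment": label,
                    "dose": dose,
                    "replicate": rep,
                }
            )
    return SampleMetadata(frame=pd.DataFrame(rows))


def _moran_sample(rng, meta_p: np.ndarray, depth: int, m: float,
                  burn_in_factor: int = 10) -> np.ndarray:
    """One local community after a burn-in of ``burn_in_factor * depth``
    death-replacement events.

    The community starts at the analytic stationary composition - a
    Dirichlet draw with concentration theta = N*m/(1-m), the coalescent
    fixed point of the death-replacement dynamics - so the burn-in
    decorrelates rather than having to mix from a distant state (mixing
    from an arbitrary state needs ~N/m events, which exceeds the burn-in
    budget at small m).
    """
    n_otus = meta_p.size
    if m >= 1.0 - 1e-12:
        x = meta_p
    else:
        theta = depth * m / (1.0 - m)
        x = rng.dirichlet(np.clip(theta * meta_p, 1e-10, None))
        x = x / x.sum()
    community = rng.choice(n_otus, size=depth, p=x)
    events = burn_in_factor * depth
    death = rng.integers(depth, size=events)
    immigrant = rng.random(events) < m
    meta_draw = rng.choice(n_otus, size=events, p=meta_p)
    local_parent = rng.integers(depth, size=events)
    for t in range(events):
        if immigrant[t]:
            community[death[t]] = meta_draw[t]
        else:
            community[death[t]] = community[local_parent[t]]
    return np.bincount(community, minlength=n_otus)


def simulate_neutral(config: SimulationConfig) -> tuple[OtuTable, SampleMetadata]:
    """Independent neutral local communities (drift + immigration).

    Each sample evolves a community of ``depth`` individuals by
    death-replacement: with probability ``m`` the replacement immigrates
    from the metacommunity, otherwise it is the offspring of a random
    local individual.  ``m = 1`` reduces to multinomial sampling of the
    metacommunity; ``m -> 0`` drifts to near-monodominance.
    """
    if not (0 < config.m <= 1):
        raise ValueError(f"m must be in (0, 1], got {config.m}")
    if config.depth < 100:
        raise ValueError("depth must be at least 100")
    meta_p = metacommunity(config)
    meta = _metadata_frame(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    counts = np.empty((config.n_samples, config.n_otus), dtype=np.int64)
    for i in range(config.n_samples):
        counts[i] = _moran_sample(rng, meta_p, config.depth, config.m)
    table = OtuTable(
        counts=counts,
        sample_ids=list(meta.frame["sample_id"]),
        otu_ids=_otu_ids(config.n_otus),
    )
    return table, meta


def simulate_gradient(
    config: SimulationConfig,
    traits: pd.Series,
) -> tuple[OtuTable, SampleMetadata]:
    """Dose-dependent selection on a phylogenetically conserved trait.

    Per treatment, sampling weights are the metacommunity tilted by
    ``exp(selection_strength * dose_scaled * trait)``, with the dose
    log1p-scaled so the top dose does not annihilate the rare tail;
    samples are independent multinomial draws of ``depth`` reads.
    ``selection_strength = 0`` reduces to neutral sampling with m = 1.
    """
    if config.selection_strength < 0:
        raise ValueError("selection_strength must be non-negative")
    meta_p = metacommunity(config)
    trait_vec = traits.reindex(_otu_ids(config.n_otus)).to_numpy()
    if np.isnan(trait_vec).any():
        raise ValueError("traits must cover every simulated OTU")
    meta = _metadata_frame(config)
    max_dose = max(d for _, d in config.treatments)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    counts = np.empty((config.n_samples, config.n_otus), dtype=np.int64)
    row = 0
    for label, dose in config.treatments:
        dose_scaled = np.log1p(dose) / np.log1p(max_dose) if max_dose > 0 else 0.0
        logw = np.log(meta_p) + config.selection_strength * dose_scaled * trait_vec
        w = np.exp(logw - logw.max())
        w /= w.sum()
        for _ in range(config.n_samples_per_treatment):
            counts[row] = rng.multinomial(config.depth, w)
            row += 1
    table = OtuTable(
        counts=counts,
        sample_ids=list(meta.frame["sample_id"]),
        otu_ids=_otu_ids(config.n_otus),
    )
    return table, meta


def tiny_config(seed: int = 0, **overrides) -> SimulationConfig:
    """50 OTUs x 12 samples (4 treatments x 3 replicates), depth 1000 -
    the seconds-scale fixture."""
    defaults = dict(
        n_otus=50,
        n_samples_per_treatment=3,
        treatments=[("Control", 0.0), ("PYR10", 10.0), ("PYR100", 100.0),
                    ("PYR500", 500.0)],
        depth=1000,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def paper_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """2,000 OTUs x 30 samples (5 treatments x 6 replicates), depth 39,134."""
    defaults = dict(seed=seed)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def make_fixtures(out_dir, seed: int = 0, scales: tuple = ("tiny", "paper-like")) -> dict:
    """Write paired neutral + gradient fixtures with ground-truth JSON.

    Per scale: ``<scale>_<mode>_table.tsv``, ``<scale>_metadata.tsv``,
    ``<scale>_tree.nwk`` and ``<scale>_truth.json``.  Byte-identical for a
    fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for scale in scales:
        config = tiny_config(seed) if scale == "tiny" else paper_like_config(seed)
        tag = scale.replace("-", "_")
        tree, traits = simulate_phylogeny(
            config.n_otus, seed=config.seed, trait_var=config.trait_model_var
        )
        neutral_table, meta = simulate_neutral(config)
        gradient_table, _ = simulate_gradient(config, traits)
        paths = {
            "neutral_table": out / f"{tag}_neutral_table.tsv",
            "gradient_table": out / f"{tag}_gradient_table.tsv",
            "metadata": out / f"{tag}_metadata.tsv",
            "tree": out / f"{tag}_tree.nwk",
            "truth": out / f"{tag}_truth.json",
        }
        write_otu_table(neutral_table, paths["neutral_table"])
        write_otu_table(gradient_table, paths["gradient_table"])
        write_metadata(meta, paths["metadata"])
        tree.write(path=str(paths["tree"]), schema="newick",
                   suppress_rooting=True)
        n_deg = max(1, int(round(config.degrader_fraction * config.n_otus)))
        degraders = list(traits.sort_values(ascending=False).index[:n_deg])
        truth = {
            "scale": scale,
            "m": config.m,
            "selection_strength": config.selection_strength,
            "depth": config.depth,
            "n_otus": config.n_otus,
            "treatments": config.treatments,
            "degrader_otus": degraders,
            "seed": config.seed,
        }
        paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
        written[scale] = {k: str(v) for k, v in paths.items()}
    return written
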