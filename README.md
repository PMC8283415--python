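# assemblage

Community-ecology inference for abundant and rare microbial subcommunities
along a stressor gradient.

Soil amplicon surveys routinely ask how a pollutant dose reshapes a
bacterial community: which taxa become dominant, whether the community's
diversity resists the disturbance, and whether the reshaping is driven by
deterministic selection or by stochastic dispersal and drift.  `assemblage`
packages the full chain of statistics used to answer those questions on an
OTU count table (samples × OTUs), sample metadata (treatment, dose,
replicate) and a rooted phylogeny:

* **Partitioning** — per treatment, OTUs are *abundant* (relative abundance
  ≥ 1% in at least one sample), *rare* (treatment mean < 0.01%) or
  *moderate*, with tracking of class transitions along the gradient.
* **Diversity & resistance** — Shannon (nats), Gini–Simpson, Bray–Curtis,
  and the bounded resistance index RS = 1 − 2|D₀|/(C₀ + |D₀|) of perturbed
  Shannon against the control mean.
* **Niche breadth** — Levins' B_i = 1/Σ_j P_ij² per OTU and the mean width
  per community or subcommunity.
* **Sloan neutral community model** — occurrence frequency vs mean relative
  abundance, f̂(p) = 1 − BetaCDF(d; Nmp, Nm(1−p)); one-parameter least
  squares fit of the immigration rate m, R², Nm, and an
  above/neutral/below partition by 95% Wilson bands.
* **Assembly null models** — abundance-weighted βMNTD with a tip-shuffling
  null (βNTI) and probabilistic Raup–Crick on Bray–Curtis (RC_Bray),
  classifying each sample pair as homogeneous/variable selection,
  homogenizing dispersal, dispersal limitation or undominated
  (βNTI beyond ±2; RC beyond ±0.95).
* **Co-occurrence networks** — Spearman correlation networks with an
  RMT-guided threshold (nearest-neighbour eigenvalue spacing scan), node
  topology (degree, betweenness, clustering), abundant–rare interaction
  networks and a scale-free R² check.
* **Synthetic data** — a neutral (Moran death–replacement) simulator, a
  dose–selection gradient simulator on Brownian traits over a Yule
  phylogeny, and fixture writers, so every stage is testable against known
  ground truth.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
import numpy as np
import assemblage as asm
from assemblage.synthetic_data import paper_like_config, simulate_phylogeny, simulate_gradient

cfg = paper_like_config(seed=7)          # 2000 OTUs, 5 doses x 6 reps, depth 39134
tree, traits = simulate_phylogeny(cfg.n_otus, seed=7)
table, meta = simulate_gradient(cfg, traits)   # dose-dependent selection on traits

cls = asm.classify(table, meta)
rel = asm.to_relative(table)
for t in ("Control", "PYR500"):
    otus = cls.otus_of(t, "abundant")
    sidx = [table.sample_index(s) for s in meta.samples_of(t)]
    oidx = [table.otu_ids.index(o) for o in otus]
    print(t, len(otus), round(float(rel[np.ix_(sidx, oidx)].sum(axis=1).mean()), 3))
# Control 11 0.328
# PYR500 15 0.829

fit = asm.fit_ncm(table)
print(round(fit.r2, 3), round(fit.m, 3))       # 0.707 0.583

from assemblage.diversity import treatment_resistance
print(treatment_resistance(table, meta).groupby("treatment", sort=False)["RS"].mean().round(3))
# PYR1      0.992
# PYR10     0.910
# PYR100    0.560
# PYR500    0.339
```

A dozen abundant OTUs carry 33% of the reads in the control but 83% at the
top dose, the neutral occurrence-frequency fit is decent (R² ≈ 0.71,
fitted immigration ≈ 0.58), and Shannon-based resistance decays from 0.99
at the lowest dose to 0.34 at the highest — the dose-dependent selection
built into the generator, recovered by each statistic.  On the smaller
fixture the null models tell the same story from pairwise turnover:

```python
from assemblage.synthetic_data import tiny_config
cfg = tiny_config(seed=7)                # 50 OTUs, 4 doses x 3 reps, depth 1000
tree, traits = simulate_phylogeny(cfg.n_otus, seed=7)
table, meta = simulate_gradient(cfg, traits)
res = asm.assembly_processes(table, tree, meta, n_null=199, seed=1)
print(res.fractions().round(2)["variable_selection"])
# Control    0.00
# PYR10      0.00
# PYR100     0.50
# PYR500     0.75
```

The fraction of sample pairs classified as variable selection rises from 0
to 75% along the gradient.

The same operations are available from the shell
(`assemblage simulate|rarefy|partition|diversity|resistance|niche|ncm|assembly|network`),
and the `analysis/` directory holds numbered narrative drivers
(`01_simulate.py` … `06_network.py`) that run each stage on the synthetic
fixtures and write summary tables under `results/`.

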