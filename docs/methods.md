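# Methods

`assemblage` implements the inference chain used to study how abundant and
rare soil-bacterial subcommunities respond to a stressor gradient (the
motivating system is pyrene-spiked soil microcosms: 5 dose levels × 6
replicate microcosms, 16S OTU tables rarefied to a common depth).  This
note records the models, the defaults and why, what the synthetic data do
and do not emulate, and the numerical choices.

## Data model

An `OtuTable` is an integer count matrix (samples × OTUs) with string ids;
all file formats carry ids, never positional indices.  Rarefaction is
multivariate-hypergeometric subsampling without replacement to a fixed
depth, with the seed an explicit argument.  OTUs that end up all-zero are
retained (and flagged) so id spaces stay aligned across treatments;
downstream statistics ignore all-zero columns.

## Abundance partitioning

Per treatment, an OTU is

* **abundant** — relative abundance ≥ 1% (`abundant_cut = 0.01`) in at
  least one sample of the treatment (a taxon spiking in a single replicate
  counts);
* **rare** — mean relative abundance across the treatment's samples
  < 0.01% (`rare_cut = 1e-4`), provided it is not abundant;
* **moderate** — everything in between; **absent** — zero everywhere.

The mixed convention (max-over-samples for abundant, treatment mean for
rare, abundant wins on conflict) follows the common usage in the
abundant/rare literature and makes the classes disjoint and exhaustive by
construction.  A pooled mode (one global classification) exists for
sensitivity analysis.  Note the rare class is unreachable when sampling
depth × `rare_cut` < 1 (e.g. depth 1,000); tests that need a populated
rare class at small depth raise the cutoff explicitly.

## Diversity and resistance

Shannon entropy is reported in nats, Simpson as Gini–Simpson 1 − Σp².
β-diversity is Bray–Curtis.  Resistance of a perturbed community relative
to the control uses the bounded index

    RS = 1 − 2|D0| / (C0 + |D0|),  D0 = C0 − P0,

with C0 the control-mean Shannon and P0 the perturbed sample's Shannon
(Orwin & Wardle's form): RS = 1 at no change, 0 at total loss, strictly
decreasing in |D0|, bounded in (−1, 1].  This functional form is an
assumption — studies in this area typically cite it without printing it.
Per-replicate values are computed against the control-treatment mean;
treatment-level resistance is the mean of replicate values.

## Niche breadth

Levins' B_i = 1/Σ_j P_ij² over resource states j, where P_ij is the share
of OTU i's abundance found in state j; B ranges from 1 (specialist) to r
(uniform generalist).  States default to individual samples (r = number of
samples); a treatment-level aggregation is provided.  Absent OTUs are
excluded from the community mean rather than contributing B = 0, because B
is undefined for an all-zero vector.

## Sloan neutral community model

Under drift plus immigration (probability `m` per death–replacement into a
local community of `N` individuals), the stationary relative abundance of
a taxon with metacommunity mean p is approximately Beta(Nmp, Nm(1−p)); its
predicted occurrence frequency across samples is

    f̂(p) = 1 − BetaCDF(d; Nmp, Nm(1−p)),

with detection limit d = 1/N (one read at the rarefaction depth).  `m` is
fitted by bounded one-dimensional least squares on (1e-6, 1]; N is fixed
to the mean sample depth, not co-estimated, because the model is
effectively one-parameter given N.  R² = 1 − SSE/SST can be negative for
anti-neutral data and is reported unclamped.  OTUs are partitioned
above/within/below a 95% Wilson binomial band around f̂ at n = number of
samples.

Two systematic biases of this estimator, measured with the package's own
simulators, are worth knowing:

* the Sloan beta is a diffusion approximation of the death–replacement
  process; the exact stationary concentration is Nm/(1−m), so the fit
  recovers roughly m/(1−m) rather than m (+11% at m = 0.1; saturating at
  the m = 1 bound once m > 0.5);
* approximating the probability of detection (count ≥ 1) by the continuous
  tail P(x > 1/N) adds roughly +20% at N = 1,000.

Consequently fitted m from Moran-process data at m = 0.1, N = 1,000 comes
back at ≈ 0.133 (median over 20 simulations).  Both biases shrink as N
grows and are properties of the model formula, not of the optimiser.

## Assembly null models

**βMNTD / βNTI.**  Abundance-weighted between-community mean nearest taxon
distance: 0.5·[Σ_i f_ik · min_{j∈l} D_ij + Σ_j f_jl · min_{i∈k} D_ij]
with D the patristic distance matrix.  The null shuffles tip identities
across the whole tree (regional pool = every OTU in the scope), keeping
every community's richness and abundances fixed; βNTI is the z-score of
the observed value against `n_null` (default 999) shuffles.  D is computed
once by a postorder merge (O(n²)); nulls permute matrix indices and never
re-traverse the tree, so 30 samples × 2,000 OTUs × 999 nulls runs in
minutes on one CPU.  If both communities contain exactly the same taxa,
βMNTD is 0 under every permutation and βNTI is undefined (reported NaN
with a warning) — dense subcommunity tables, e.g. a handful of abundant
OTUs present in every sample, hit this case legitimately.

**RC_Bray.**  For each sample pair, null pairs preserve each sample's
richness (membership drawn without replacement with probability ∝
occurrence frequency) and total abundance (individuals assigned
multinomially ∝ regional mean relative abundance, after guaranteeing one
individual per drawn taxon).  RC = 2·[(#null BC < obs) + ½·ties]/n_null − 1
∈ [−1, 1].  The regional pool is estimated from the analysed table by
default and can be pinned externally (`pool_freq` / `pool_abund`) — the
right choice when a subcommunity is ranked against the whole community's
pool, and what makes the self-calibration experiment exact.

**Process classification.**  βNTI ≤ −2 homogeneous selection; ≥ 2 variable
selection; otherwise RC ≤ −0.95 homogenizing dispersal, RC ≥ 0.95
dispersal limitation, |RC| < 0.95 undominated.  Boundary equalities are
deterministic (selection / dispersal side).  Pair scope defaults to
within-treatment pairs plus control-vs-treatment pairs, grouped by
treatment; per-group fractions are computed over classifiable pairs only.

## Co-occurrence networks

Spearman ρ is Pearson on mid-ranks (so constant OTU vectors degrade to NaN
pairs rather than errors), after a prevalence filter (default: present in
≥ 1/3 of samples).  The RMT threshold scan zeroes |ρ| < t for t =
0.30…0.99 (step 0.01), unfolds the eigenvalue spectrum through a
degree-5 polynomial fit of the cumulative spectral function, bins
nearest-neighbour spacings into 20 bins on [0, 3], and accepts the
smallest t whose spacing distribution is consistent with Poisson e^(−s)
(χ² p > 0.05).  The unfolding parameters are free in the RMT literature;
these values are stable for matrices of order 10²–10³.  When no threshold
qualifies the fallback is |ρ| ≥ 0.8, flagged in the return value.  On a
block-correlated matrix the accepted threshold sits *below* the
within-block correlation: removing between-block noise leaves independent
blocks whose superposed spectra are Poisson, which is exactly the point of
the scan — signal edges survive.  Betweenness is reported raw (so the star
closed form (n−1)(n−2)/2 holds) alongside a normalised column; the
scale-free check is the R² of a least-squares log-frequency vs log-degree
line, requiring ≥ 4 distinct degrees.

## Synthetic data

The generators emulate the post-OTU-picking state of a rarefied amplicon
survey; their defaults are the study conditions, not tuning knobs:

* metacommunity: lognormal(μ = 0, σ = 2) relative abundances — a few
  dominants over a long rare tail;
* design: treatments Control/1/10/100/500 mg·kg⁻¹ × 6 replicates, depth
  39,134 reads ("paper-like"), or 4 doses × 3 replicates × 50 OTUs at
  depth 1,000 ("tiny");
* phylogeny: Yule tree scaled to unit depth (pendant edges extended by the
  waiting time to the next, never-realised, speciation so the newest
  cherry has positive length), with a Brownian trait (σ² = 1 per unit
  depth) as each tip's environmental optimum;
* neutral mode: per sample, a death–replacement (Moran) community of
  `depth` individuals with immigration `m` (default 0.65, the order
  implied by Nm ≈ 25,000 at N ≈ 39,000), initialised at the analytic
  stationary composition (Dirichlet with concentration Nm/(1−m)) and run
  for a 10×depth-event burn-in — initialising at stationarity matters
  because mixing from an arbitrary state takes ~N/m events;
* gradient mode: independent multinomial samples with weights ∝
  metacommunity × exp(s · dose_scaled · trait), s = 3 by default and dose
  log1p-scaled so the top dose does not annihilate the rare tail.  At
  s = 0 this reduces exactly to neutral sampling with m = 1.  Both modes
  share the metacommunity, so neutral-vs-gradient contrasts isolate the
  selection term.

What the simulators do **not** emulate: spatial autocorrelation between
replicates (samples are independent, so genuine dispersal limitation
cannot be regenerated — null-model tests target type-I calibration and
selection detection, not the dispersal classes), sequencing error, copy
number variation, or compositional overdispersion beyond multinomial.
Passing tests therefore demonstrate correctness of the statistics and
their calibration under known ground truth, not that real soil data would
show the same process fractions.

## Problem sizes used in the checks

Null-model calibration runs on the tiny fixture (50 OTUs × 12 samples, 999
nulls).  The selection positive control runs at 200 OTUs: nearest-taxon
statistics need a few hundred tips before a selected clade reliably moves
βMNTD (measured median extreme-dose βNTI across 21 replicates: 1.5 at 50
OTUs vs 2.5 at 200 OTUs at identical selection strength), so 50 tips is an
underpowered design for that check.  Neutral-model recovery uses 20
simulations at m = 0.1, N = 1,000, 30 samples.  The direction checks run
at the full 2,000 × 30 × 39,134 scale, where generation is multinomial and
cheap.

## Known limitations

* The NCM fit inherits the two approximation biases above; treat fitted m
  as an effective immigration index, not an unbiased rate.
* βNTI is undefined for pairs with identical membership; small abundant
  subcommunities produce such pairs routinely.
* Spearman networks from 6 replicates per treatment are statistically
  weak; the RMT scan (or the flagged 0.8 fallback) controls density but
  cannot create power that is not there.
* The rare class requires depth × rare_cut ≥ 1 to be reachable.
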