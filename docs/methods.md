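# Methods

`riverbiome` implements the statistical core of a river-wide 16S
microbiome biogeography analysis: OTU-table processing, alpha/beta
diversity, permutation statistics, dendritic river-network distance
measures, season-associated taxa detection, co-occurrence network
density, and Sloan neutral-community-model fitting — together with a
metacommunity simulator that generates datasets with exactly the
structure these statistics assume, so the whole pipeline is testable
end to end with known ground truth.

## OTU-table processing

The unit of analysis is an integer OTU × sample count matrix with
optional per-OTU taxonomy. Before any statistic, two filters are
applied: OTUs with a table-wide total of one or two reads (singletons
and doubletons) are removed, as are OTUs whose overall relative
abundance — OTU total over the grand total — is below 0.01%
(`min_rel_abundance=1e-4`). The abundance filter is interpreted
table-wide because it is applied once, ahead of all analyses; a
per-sample variant (`per_sample=True`, requiring the threshold in at
least one sample) is exposed for sensitivity analyses. Depth
normalization is rarefaction without replacement: each sample is an
independent multivariate-hypergeometric draw at the chosen depth,
seeded, with samples below the target depth either rejected (default)
or dropped explicitly.

Occupancy (occurrence frequency) is the fraction of samples in which an
OTU has a nonzero count. An OTU is **persistent** when its occupancy
strictly exceeds 0.30 ("more than 30%"), else **transient**; the
boundary value 0.30 itself is transient.

## Diversity

Alpha diversity follows the classic abundance-based estimators: Chao1
(`S_obs + F1²/2F2`, or `S_obs + F1(F1−1)/2` when no doubletons exist),
ACE with the conventional rare/abundant split at 10 reads and the
coefficient of variation floored at 0 (degenerating to Chao1 when every
rare OTU is a singleton), Good's coverage `1 − F1/N`, Shannon with the
natural logarithm, and Simpson reported as dominance `D = Σ p_i²`
(`1 − D` via a flag). The log base and Simpson variant are conventions
of this package, stated rather than inherited. Rarefaction curves use
the exact hypergeometric expectation
`E[S(n)] = Σ_i (1 − C(N−N_i, n)/C(N, n))` instead of Monte-Carlo
resampling; the expectation equals observed richness at full depth by
construction. Beta diversity is Bray-Curtis dissimilarity
(`Σ|x_i−y_i| / Σ(x_i+y_i)`), computed on per-sample relative abundances
by default so sequencing depth differences do not masquerade as
community turnover.

## Permutation statistics

ANOSIM ranks all pairwise dissimilarities (mid-ranks for ties) and
contrasts between- versus within-group mean ranks, scaled by
`n(n−1)/4`, giving R ∈ [−1, 1]; a constant matrix yields R = 0. Mantel
correlates the upper triangles of two distance matrices (Spearman by
default, via a rank transform of each triangle) under simultaneous
row/column permutation of one matrix; the default alternative is
one-sided positive, matching its distance-decay use, with two-sided
available. Both tests use the add-one estimate
`p = (1 + #{permuted ≥ observed}) / (1 + n_permutations)` with 999
permutations by default, so p is never exactly 0, and both accept an
exact mode that enumerates every permutation on small instances
(feasible up to n ≈ 8–9), in which case p is the fraction of the full
permutation distribution at or above the observed statistic. All
permutation draws flow from an explicit seed.

The moving-window analysis quantifies turnover along an ordered station
sequence: stations with several samples contribute the mean of their
relative-abundance profiles, and each consecutive pair is scored
`100·(1 − r)` with r the Pearson correlation (Spearman via a flag).
The value is deliberately uncapped — anticorrelated neighbouring
profiles score above 100 — because capping would hide exactly the
sharp-transition signal the analysis looks for.

## Dendritic river-network measures

A river network is a rooted in-tree (single outlet, every reach
draining downstream) with reach lengths (km) on edges and subcatchment
areas (km²) on nodes. Three per-site scalars are computed by a single
topological-order accumulation: **site catchment area** (summed
subcatchment areas of the site and everything upstream), **cumulative
dendritic distance** (summed lengths of all headwater-to-site paths,
where headwaters are in-degree-0 termini), and **mean dendritic
distance** (their average — a residence-time proxy). A headwater site
has one trivial path of length 0. Pairwise geographic distance between
sites is the absolute difference of the chosen scalar — the minimal
monotone construction when the source analysis defines only per-site
scalars — with along-network flow distance between site pairs available
as a fourth option (`which="flow"`), since the two readings cannot be
distinguished from the original description.

## Season-associated taxa and co-occurrence networks

Among persistent OTUs, spring and autumn relative abundances are
compared per OTU with a two-sided Mann-Whitney U test — exact when the
pooled values are tie-free and both groups have ≤ 25 samples, otherwise
the normal approximation with tie correction; Welch's t on
log10-transformed abundances (pseudocount 1e-6) is available as an
alternative. p-values are Benjamini-Hochberg adjusted within the tested
(per-habitat) OTU set, and an OTU with adjusted p < 0.05 is labelled
with the season of greater median abundance (equal medians → no label).
The rank test was chosen for distribution-freeness on sparse,
overdispersed count-derived data.

Co-occurrence networks connect OTU pairs whose Spearman correlation
across samples passes both an (FDR-adjusted, by default) significance
threshold (p < 0.01) and an effect-size threshold (|ρ| > 0.5) — a
superset of the two threshold regimes in common use; adjustment can be
disabled. Constant OTUs carry no rank information and are simply
excluded. The **network density** `d = edges / nodes` may exceed 1
under this definition (a complete graph on k nodes has d = (k−1)/2).
Phyla are grouped by the share of their season-associated OTUs:
autumn-dominated at ≥ 75% autumn (inclusive), spring-dominated
symmetrically, otherwise mixed; the 0.75 cutoff is this package's
choice, as no numeric rule exists in the source description.

## Neutral community model

The Sloan formulation models each local community as N individuals
under birth-death-immigration: a dead individual is replaced from the
metacommunity with probability m, otherwise by local reproduction. At
stationarity the local relative abundance of an OTU with metacommunity
abundance p is approximately Beta(Nmp, Nm(1−p)), so its expected
occurrence frequency across communities is

    freq(p) = 1 − I_d(Nmp, Nm(1−p)),

the upper tail beyond the detection limit d, with I the regularized
incomplete beta function. Fitting requires equal-depth samples
(subsample first); N is the per-sample depth and d defaults to one read
(1/N), the conventional instantiation for amplicon data, both
overridable. Because m is the sole free parameter, the fit is a bounded
scalar least-squares search on (1e-6, 1] to absolute tolerance 1e-8
rather than a generic nonlinear solver. R² = 1 − SS_res/SS_tot is
reported as-is and may be negative. OTUs absent from every sample are
excluded.

OTUs are partitioned against a 95% band around the predicted frequency:
**above** when observed occupancy exceeds the upper bound, **below**
under the lower bound, else **neutral**. The default band is the exact
central binomial prediction interval — quantiles of Bin(n_samples,
predicted)/n — rather than a normal-approximation interval: observed
frequencies of exactly 0 or 1 are high-probability outcomes whenever
the predicted frequency is near the extremes, and any interval that
cannot reach 0 or 1 (Wilson included) misclassifies those outcomes
systematically, deflating measured coverage from the nominal 95% to
~84% in our regeneration checks. The Wilson score interval remains
available (`ci_method="wilson"`) for comparison with analyses that use
it.

## The synthetic-data generator

The generator emulates the sampling design the statistics expect: a
random dendritic network (a mainstem chain of stations plus tributary
headwaters) spanning five landform classes in fixed downstream order
(mountain → foothill → basin → foothill-mountain → plain), with paired
water/sediment samples per station in two seasons.

* **Metacommunity**: lognormal rank-abundance (σ = 2.0 by default,
  a heavy-tailed shape typical of 16S surveys; log-series optional).
* **Neutral assembly**: a Moran process per station — N individuals;
  each step kills one uniformly and replaces it from the metacommunity
  with probability m or by copying one of the surviving N−1 individuals
  — run for `burn_in_generations × N` steps (default 20 generations,
  several multiples of the ~1/m-generation relaxation time) from a
  multinomial initialization, vectorized across stations. Habitat
  immigration rates default to water 0.19 and sediment 0.15, the
  dispersal contrast the analyses are designed to detect.
* **Species sorting**, applied as multiplicative re-weighting of the
  local composition *after* the neutral dynamics and *before* the
  multinomial read draw, so the neutral and selective components stay
  separable and ground truth exact: (i) season effects on a random 20%
  of OTUs (log2 fold 2 in water, 0.5 in sediment — seasonality is a
  water-column phenomenon here — with 70% of affected OTUs favoured in
  autumn); (ii) landform effects on a random 20% of OTUs, each drawing
  an independent ±log2-fold-2 multiplier per landform, so crossing any
  landform boundary re-draws the selective regime of the whole affected
  subset; (iii) an optional smooth along-river turnover gradient
  (`distance_turnover_strength`, off by default) in which each OTU's
  log-weight drifts linearly with normalized mainstem position —
  enabling it produces the distance-decay structure probed by the
  Mantel analysis.
* **Observation**: a multinomial draw of `depth` reads (default 1000)
  per sample.

Effect sizes are log2 fold changes throughout. All randomness descends
from one root seed through spawned generators, so identical
configurations reproduce byte-identical outputs.

What the generator does **not** emulate: spatial autocorrelation of the
neutral component between neighbouring stations (stations drift
independently around the shared metacommunity; real rivers advect
upstream communities downstream), taxonomic structure in the
correlations (synthetic taxonomy assigns phyla at random), chimeras,
PCR/primer bias, and variable sequencing depth. Passing tests therefore
demonstrate that the statistics recover planted structure of realistic
magnitude under neutral + multinomial noise — not that any particular
real dataset satisfies the model.

Known bias worth stating: fitting the stationary Beta approximation
with parameters Nmp to communities generated by the discrete Moran
process recovers m/(1−m) rather than m (≈ 0.176 for a true 0.15) —
an inherent, small, conservative-direction discrepancy between the
diffusion approximation and the finite-N process, visible in the
parameter-recovery tests and bounded well within their tolerance.

## Benchmarks and problem sizes

The test suite's study-scale benchmarks run at the generator defaults:
S = 300 OTUs, N = 1000, 50 stations, depth 1000. Parameter recovery
uses 20 seeded replicates; confidence-band coverage regenerates
occupancy 50 times from the fitted binomial model; false-discovery
control averages 50 null replicates (200 OTUs, 10 samples per season,
multinomial observation of the metacommunity — the generator's m = 1
limit, which is the exact null of the seasonal test). Sensitivity to
planted season effects is computed over planted OTUs that are both
persistent and *detectable* — baseline expectation of at least 2 reads
per sample: at 24,000-read depths the 0.01% abundance filter removes
sub-detection OTUs automatically, but at a 1000-read desk scale that
same relative threshold leaves OTUs in the table whose expected count
is a fraction of a read, and no two-sample test can see an effect on an
OTU that is absent from both groups. Measured this way, sensitivity at
the default 4× effect averages ≈ 0.96; with the undetectable stratum
included it would be dominated by the sequencing depth rather than by
the test.

## Numerical choices

Mid-ranks everywhere ties occur; permutation p-values use the add-one
rule; float comparisons in permutation counting use a 1e-12 tolerance
so exact ties count as "at least as extreme". The beta tail is
evaluated with `scipy.special.betainc`, exact at the degenerate
endpoints p ∈ {0, 1}. The ACE coverage estimator falls back to Chao1
when all rare OTUs are singletons (estimated coverage zero). Stage
seeds in the CLI derive from the root seed as
`(seed·1000003 + stage_index) mod 2³¹`, so stages are individually
reproducible and re-runnable.
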