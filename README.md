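# riverbiome

Statistics for the biogeography of riverine bacterial communities —
paired water and sediment 16S samples taken at stations along a
dendritic river network, over multiple seasons. The package is for
microbial ecologists asking the classic metacommunity questions of such
surveys: how much of community assembly looks neutral (dispersal +
drift from a shared species pool) versus selected (species sorting by
landform, season, position along the river), and which taxa carry the
seasonal signal.

It covers the full statistical pipeline downstream of an OTU table:

* **OTU-table processing** — classic TSV I/O, singleton/doubleton and
  0.01%-abundance filters, relative abundance, seeded rarefaction
  (multivariate hypergeometric), occupancy.
* **Diversity** — ACE, Chao1, Good's coverage, Shannon, Simpson; exact
  rarefaction curves; Bray-Curtis dissimilarity matrices.
* **Permutation statistics** — ANOSIM and Mantel (999 permutations,
  seeded, exact enumeration on small instances) and a moving-window
  turnover rate `100·(1 − r)` between consecutive stations.
* **River-network measures** — site catchment area, cumulative and mean
  dendritic distance on a rooted in-tree of reaches, and pairwise
  geographic distance matrices for distance-decay analysis.
* **Season-associated taxa** — persistent/transient classification
  (occupancy > 30%), Mann-Whitney + Benjamini-Hochberg season
  association, Spearman co-occurrence networks with the density
  statistic `d = edges/nodes`, and phylum-level seasonality groups.
* **Neutral model** — Sloan's birth-death-immigration model: occurrence
  frequency `freq(p) = 1 − I_d(Nmp, Nm(1−p))`, one-parameter
  least-squares fit of the immigration rate m, R², and partitioning of
  OTUs above/within/below a 95% prediction band.
* **Synthetic data** — a seeded metacommunity simulator (lognormal
  species pool, per-station Moran dynamics, configurable species
  sorting, multinomial sequencing noise) that generates OTU table,
  metadata, river network and ground truth for end-to-end testing.

The model and design choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

```python
import riverbiome as rb

# a synthetic survey: 20 stations x {water, sediment} x {spring, autumn}
cfg = rb.SimulationConfig(n_stations=20, n_otus=200, seed=42)
ds = rb.simulate_river_dataset(cfg)
table = rb.filter_otus(ds.table)
meta = ds.metadata.set_index("sample_id")
print(f"{table.n_otus} OTUs x {table.n_samples} samples after filtering")

# is the water community seasonally structured?
water = table.select_samples(
    [s for s in table.sample_ids if meta.loc[s, "habitat"] == "water"])
dm = rb.bray_curtis_matrix(water)
res = rb.anosim(dm, {s: meta.loc[s, "season"] for s in water.sample_ids}, seed=0)
print(f"ANOSIM by season (water): R = {res.statistic:.3f}, p = {res.p_value:.3f}")

# how neutral does spring water look?
spring = water.select_samples(
    [s for s in water.sample_ids if meta.loc[s, "season"] == "spring"])
even = rb.subsample_to_depth(spring, int(spring.sample_totals.min()), seed=0)
fit = rb.fit_neutral_model(even)
pct = fit.partition_percentages()
print(f"neutral fit (water, spring): m = {fit.m:.3f}, R^2 = {fit.r_squared:.3f}")
print(f"partitions: {pct['above']:.1f}% above / {pct['neutral']:.1f}% neutral "
      f"/ {pct['below']:.1f}% below")
```

prints

```
171 OTUs x 80 samples after filtering
ANOSIM by season (water): R = 0.655, p = 0.001
neutral fit (water, spring): m = 0.183, R^2 = 0.868
partitions: 1.2% above / 92.6% neutral / 6.2% below
```

The generator planted a season effect on 20% of OTUs in water, and the
ANOSIM detects it (R well above 0; p at the permutation floor of
1/1000). The neutral fit recovers an immigration rate near the
configured water value with a high R², and — because the underlying
assembly really is neutral plus mild selection — most OTU occupancies
sit inside the model's 95% band.

The same pipeline runs from the shell:

```sh
riverbiome all --output-dir out --seed 7           # simulate + all stages
riverbiome neutral --config my_config.yaml         # one stage, YAML config
```

Each stage writes TSV/JSON artifacts under `out/<stage>/` and records
parameters and seed in `out/manifest.json`; identical config + seed
reproduces every file byte for byte. Real data enter through the
`inputs:` config block (OTU-table TSV, metadata TSV, river-network edge
list) instead of the `simulate:` block.

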