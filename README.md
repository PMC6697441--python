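# microrepeat

Partitioning microbiome diversity variation into **biological (among-host)**
and **technical (within-host)** components.

When the same gut (or soil core, or leaf surface) is sequenced several times
— with different DNA-isolation protocols, or as repeated subsamples — the
16S count tables disagree with each other. How much of the variation you
measure across a study is real among-host biology, and how much is
measurement noise? `microrepeat` answers this with the repeated-measures
framework used in quantitative genetics: for any diversity metric measured
on replicated libraries from each host, **repeatability** (here,
*reproducibility* when replicates differ by protocol) is

    r = s²_A / (s²_A + s²_W)

where *s²_A* is the among-host and *s²_W* the within-host (among-replicate)
variance component, estimated from one-way ANOVA mean squares (with the
Lessels & Boag *n₀* correction for unequal group sizes), from a
random-effects likelihood fit, or — for community dissimilarities — from the
nested nonparametric-MANOVA sums-of-squares partition of a distance matrix.
r = 1 means the protocol contributes nothing; r = 0.5 means host and
protocol contribute equally.

The package is aimed at microbial ecologists designing or auditing
replicated amplicon studies. It provides:

* **Count prep** — rarefaction (multivariate hypergeometric, single draw),
  exclusion bookkeeping for hosts that lose replicates, count/prevalence
  filters, taxonomy-level aggregation, rarefaction curves
  (`microrepeat.counts`).
* **Diversity** — richness, Pielou evenness (log₂), Faith's PD
  (root-inclusive), Bray-Curtis, unweighted and weighted (raw or
  normalised) UniFrac, and distance-matrix construction on arbitrary
  rooted Newick trees (`microrepeat.diversity`).
* **Repeatability** — `RepeatabilityModel(...).fit()` returning variance
  components, r, and a 95% percentile CI from bootstrapping whole hosts
  (default 500 draws); a Poisson-lognormal mixed model
  (`PoissonLognormalRepeatability`) for per-taxon repeatability of counts
  with observation-level overdispersion and parametric-bootstrap CIs; and
  the three-parameter logistic fit of repeatability against log₁₀ mean
  abundance, y = α / (1 + e^((β−x)/γ)) (`microrepeat.repeatability`).
* **Inference** — Gaussian mixed-model LRTs (protocol / population /
  interaction) on alpha metrics, per-taxon Poisson-lognormal LRTs with
  ΔAIC / ΔBIC / BH-FDR decision rules, factorial PERMANOVA with stratified
  permutation, nested PERMANOVA (whole-family relabeling), Mantel tests,
  median-based Levene precision tests, distance-to-centroid dispersion with
  negative-eigenvalue correction, and the Feltz–Miller χ² test for equality
  of coefficients of variation (`microrepeat.inference`).
* **Synthetic data** — a generator that emulates a two-population,
  full-sib-family, replicated-protocol study design with known per-taxon
  log-scale variance components and closed-composition multinomial
  sequencing, retaining the latent ground truth for validation
  (`microrepeat.simulate`).

## Worked example

Simulate a study-shaped dataset (2 populations × 3 families × 6 fish × 3
protocol replicates = 108 libraries) with among-fish variance 0.5 and
within-fish variance 0.05 on the log scale, then estimate reproducibility
for three alpha metrics and Bray-Curtis:

```python
from microrepeat import (SimulationConfig, simulate_dataset, rarefy,
                         alpha_table, distance_matrix, RepeatabilityModel)

cfg = SimulationConfig(n_taxa=150, library_depth=20_000,
                       sigma2_A=0.5, sigma2_W=0.05, seed=42)
table, design, tree = simulate_dataset(cfg)
table, _ = rarefy(table, 20_000, seed=42)
fish = design.fish_for(table.library_ids)

alpha = alpha_table(table, ("richness", "evenness", "faith_pd"), tree)
for metric in alpha.columns:
    print(RepeatabilityModel(alpha[metric].to_numpy(), fish, name=metric)
          .fit(n_boot=500, seed=1).summary().round(3).to_string())

dm = distance_matrix(table, "bray_curtis")
print(RepeatabilityModel(dm, fish, name="bray_curtis")
      .fit(n_boot=500, seed=1).summary().round(3).to_string())
```

prints

```
           s2_A   s2_W      r  ci_low  ci_high  n_groups  n_obs  n_boot  seed
metric
richness  8.716  4.204  0.675    0.49    0.781        36    108     500     1
evenness  0.010  0.001  0.890   0.815    0.930        36    108     500     1
faith_pd 10.695 12.316  0.465   0.235    0.610        36    108     500     1
bray_curtis 0.056 0.008 0.879   0.847    0.900        36    108     500     1
```

Evenness and Bray-Curtis composition are dominated by among-fish signal
(r ≈ 0.88–0.89), while richness and Faith's PD — driven by rare-taxon
detection — carry much more sampling noise within fish, so their r drops
even though the replicate-level latent variance is only a tenth of the
fish-level variance. This mirrors the empirical pattern that
presence/absence-sensitive metrics reproduce worse than abundance-weighted
ones.

A command-line interface mirrors the library
(`microrepeat simulate|prep|diversity|repeatability|test-alpha|test-taxa|permanova|mantel|precision|cvtest|run`);
`microrepeat run config.yaml` executes the full pipeline and writes TSV
tables plus a JSON manifest of seeds, thresholds and per-stage audit
counts.

## Documentation

`docs/methods.md` describes the statistical models, the synthetic-data
generator and its limits, numerical choices, and known limitations.
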