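# Methods

## The repeatability framework

The package treats replicated sequencing libraries from one host as
repeated measurements of that host. For a univariate metric *y*ᵢⱼ (host
*i*, replicate *j*), the one-way random-effects model

    y_ij = μ + a_i + e_ij,   a_i ~ N(0, s²_A),   e_ij ~ N(0, s²_W)

defines repeatability r = s²_A / (s²_A + s²_W): the fraction of total
variance attributable to real among-host differences. Components are
estimated from ANOVA mean squares,

    s²_W = MS_W,   s²_A = (MS_A − MS_W) / n₀,
    n₀ = (N − Σnᵢ²/N) / (k − 1),

with *n₀* the effective replicates per host under unequal group sizes.
Negative moment estimates of s²_A are truncated at zero so r stays in
[0, 1]. Because mixed-model fitters are the common route in practice and
differ slightly from the moment estimator off balance, a profiled
(RE)ML estimator of the same model is provided
(`reml_variance_components`); for balanced groups with an interior optimum
the two coincide.

**Distance matrices.** For community dissimilarities the same partition is
computed from sums of squared dissimilarities (the nonparametric-MANOVA
identity): SS_total = (1/N)·Σ_{i<j} d²ᵢⱼ and SS_within =
Σ_g (1/n_g)·Σ_{i<j∈g} d²ᵢⱼ, with mean squares and n₀ as above. On
Euclidean distances of univariate data this reproduces the classical ANOVA
exactly (machine precision), which serves as the module's central oracle in
the test suite.

**Bootstrap CIs.** Uncertainty in r comes from resampling whole hosts with
replacement (default 500 draws, percentile 2.5/97.5). A host drawn twice
contributes two independent groups; in distance mode their cross-copy
dissimilarities are read from the original matrix, so zero-distance
cross-copy pairs count between groups, not within — this preserves the
within-host replicate structure, which a naive row resample would destroy.
Percentile intervals were chosen over BCa as the simplest method consistent
with reading the CI off the bootstrap distribution of r; simulation at the
default design (35 hosts × 3 replicates) puts their coverage near 92% at
nominal 95%, slightly liberal as percentile intervals typically are.

## Per-taxon repeatability: the Poisson-lognormal mixed model

Counts of a single taxon across equal-depth libraries are modelled as

    y_ij ~ Poisson(exp(x_ij'β + a_i + o_ij)),
    a_i ~ N(0, s²_A),   o_ij ~ N(0, s²_O),

where *o*ᵢⱼ is an observation-level random effect capturing
overdispersion (the Poisson-lognormal). Latent-scale repeatability is
r = s²_A / (s²_A + s²_O) — the link-scale variance ratio, which keeps r in
[0, 1] and matches the default reporting of repeatability estimators for
non-Gaussian responses. Original-scale repeatability is out of scope.

The marginal likelihood integrates both random effects by **nested
adaptive Gauss–Hermite quadrature** (20 nodes per dimension by default).
For each host the joint mode of (a, o₁…o_n) is found by alternating damped
Newton blocks; the outer integral over *a* is centred at the profile mode
with curvature from the Schur complement 1/s²_A + Σ λⱼ/(1 + λⱼ s²_O), and
each inner integral over *o* is re-centred at its own Laplace mode per
outer node. On a 2-host × 2-observation toy dataset this agrees with dense
nested-grid integration to < 1e-6 (the test asserts 1e-4). Parameters
(β, log s²_A, log s²_O) are maximised with L-BFGS-B; variances reaching the
log-scale lower bound are reported as boundary fits with r at the boundary,
and non-convergence is flagged rather than raised. CIs for per-taxon r use
a parametric bootstrap: simulate counts from the fit, refit, take
percentiles (default 500 replicates, seeded).

## The abundance–reproducibility curve

Per-taxon repeatability rises with abundance. The dependence is summarised
by least-squares fits of the three-parameter logistic

    y = α / (1 + e^((β − x)/γ)),

with x = log₁₀ of the across-library mean rarefied count (zeros included in
the mean), fitted separately to the point estimates and, when supplied, to
the CI bounds. α is the asymptote, β the inflection in x units, γ the
steepness at inflection. Fitting uses Levenberg–Marquardt from ≥ 5 starting
triples spanning the data range (lowest RSS wins); se(γ) comes from the
Jacobian-based covariance at the optimum and t_γ = γ/se(γ). Noiseless data
are recovered to 1e-4; the fitted curve is bounded in (0, α).

## Diversity metrics

* **Richness**: count of taxa with positive count.
* **Evenness**: Shannon H in bits divided by log₂(richness) (Pielou's
  equitability, the convention of the classic amplicon pipelines);
  undefined (NaN with a warning) below two taxa.
* **Faith's PD**: total branch length spanned by the observed taxa,
  root-inclusive by default (the path from the observed subtree's MRCA to
  the root counts, matching the classic pipeline convention); a
  `root_inclusive=False` switch drops it.
* **Bray-Curtis**: Σ|x−y| / Σ(x+y) on rarefied counts.
* **Unweighted UniFrac**: branch length unique to one sample's taxon set
  over branch length covered by the union — presence/absence only, hence
  invariant to abundance rescaling.
* **Weighted UniFrac**: Σ ℓ_b·|p_x(b) − p_y(b)| with p(b) the fraction of a
  sample's reads below branch b. Raw (non-normalised) by default, matching
  the upstream default; `normalized=True` divides by the abundance-weighted
  maximum Σⱼ dⱼ(p_xⱼ + p_yⱼ). Whether a given study normalised is often
  unstated, so both variants are first-class.

Taxa carrying counts but absent from the tree raise an error rather than
being dropped silently — silent drops corrupt the UniFrac denominator. All
metrics are verified in the tests against a naive per-edge enumeration
oracle (exhaustive presence patterns on trees ≤ 8 leaves) and against
scikit-bio's implementations.

## Count preparation

Rarefaction draws each library down to a common depth **once**, without
replacement (multivariate hypergeometric), mirroring one-shot downsampling
of real pipelines; libraries below the depth are dropped and reported, and
whole hosts falling below a minimum replicate count can then be excluded
with an audit trail. `rarefaction_curve` is the multi-iteration variant for
depth-series plots. The RNG and single-draw policy are declared defaults,
not universal conventions. Named filter presets follow common practice for
this design: taxa with ≥ 5 reads in ≥ 9 libraries (effect tests) or present
in ≥ 10 hosts (per-taxon repeatability); depths 105,000 (primary) and
74,300 (denoised-ASV comparison) are plain parameters. Taxonomy aggregation
sums counts over semicolon-delimited label prefixes (level 3 ≈ class,
level 7 ≈ species), pooling unlabeled taxa into "Unassigned", and conserves
per-library totals exactly.

## Hypothesis tests

* **Gaussian mixed-model LRTs** (alpha metrics): full vs reduced models
  with fixed protocol + population (+ interaction when tested) and random
  family and fish-within-family intercepts, fitted by **full ML, not REML**
  — the standard validity requirement when comparing fixed-effect
  structures. The statistic 2ΔlogL is referred to χ² with df = dropped
  columns (protocol 2, population 1, interaction 2 in the three-protocol,
  two-population design). Fits are delegated to statsmodels MixedLM;
  singular or non-converged fits are flagged in the result. Null
  simulations at the emulated design hold the empirical size near 0.05.
* **Per-taxon Poisson-lognormal LRTs**: same quadrature machinery with a
  fixed-effect design matrix; reports LRT, ΔAIC = AIC_reduced − AIC_full,
  ΔBIC likewise, raw and BH-adjusted p. Two named decision rules are
  first-class because both appear in practice: the strong joint rule
  (ΔAIC > 2 ∧ ΔBIC > 0 ∧ FDR p < 0.1) and the weak rule (raw p < 0.05).
  Note that 16S counts are compositional: a "taxon effect" can reflect
  community-level shifts rather than organism-specific ones.
* **PERMANOVA**: sequential (Type-I) sums of squares from the
  Gower-centred inner-product matrix, pseudo-F per term, permutation
  p-values by shuffling labels — restricted within strata (e.g. within
  fish) when given. Term order defaults to protocol, family,
  protocol×family and is configurable; family and rearing tank are
  confounded in the emulated design and outputs carry that caveat. On
  Euclidean embeddings of scalar data the pseudo-F equals the classical
  ANOVA F to machine precision.
* **Nested PERMANOVA**: F = MS_between / MS_nested-within-between with
  whole-family relabeling as the permutation unit. With 3 + 3 families only
  C(6,3) = 20 relabelings exist; the discrete p floor is reported.
  The within-fish stratified scheme permutes protocol labels within fish;
  whole-block alternatives exist and the choice is declared, not inferred.
* **Mantel**: Pearson correlation of off-diagonal entries, p by joint
  row/column permutation of one matrix.
* **Precision tests**: median-based Levene (absolute deviations from the
  host median, one-way F across protocols) for univariate metrics;
  for dissimilarities, distance from each library to its host centroid in
  the full principal-coordinate embedding, with negative-eigenvalue axes
  retained separately and their squared contribution subtracted (truncated
  at zero) — the standard correction for non-Euclidean dissimilarities.
* **Feltz–Miller CV test**: D'AD = Σ(nᵢ−1)(kᵢ−k̄)² / (k̄²(0.5+k̄²)) with k̄
  the (nᵢ−1)-weighted mean CV, referred to χ²_{k−1}. For the documented
  worked example (CVs 1.244 / 0.527), group sizes (52, 144) reproduce the
  published statistic far better than (52, 108) and are the documented
  default; with 3-decimal-rounded input CVs the statistic is reproduced to
  about three significant figures.
* **Permutation defaults**: 999 permutations, seeded, reported in the
  output; permutation p ≥ 1/(n_perm+1) always.

## The synthetic-data generator

`simulate_dataset` emulates a two-tier repeated-measures design: 2
populations × 3 full-sib families × 6 fish × 3 protocol replicates (108
libraries) by default, with a precision arm (identical-protocol subsample
replicates) available. Per taxon, fish and replicate,

    log λ_tij = b_t + offsets + a_ti + e_tij,
    a_ti ~ N(0, σ²_A),   e_tij ~ N(0, σ²_W),

and each library is **one multinomial draw** of `library_depth` reads with
probabilities ∝ λ — composition is closed at the sampling step, mirroring
relative-abundance 16S data with fixed (downsampled) totals; fixed-total
multinomial was chosen over independent Poisson for exactly that reason.
Baseline log-abundances are Normal(0, spread²) draws rank-sorted into a
lognormal rank-abundance curve, producing the rare-taxon tail needed to
exercise the abundance–reproducibility curve. Protocol and population
effects enter as optional per-taxon additive log offsets. The latent
effects are returned alongside the data so recovery tests never re-derive
ground truth from counts. Default variances (σ²_A = 0.5, σ²_W = 0.05) give
latent r ≈ 0.91, the high-reproducibility regime reported for
abundance-weighted metrics in replicated gut studies.

The generator is an assumption-faithful stand-in, not an empirical claim:
no sequencing error, chimeras or OTU-picking noise are simulated, and
lysis-bias mechanics are subsumed phenomenologically by protocol offsets.
Passing recovery tests therefore validates the estimators under the stated
model, not the realism of any particular wet-lab pipeline. DNA-yield tables
for the CV test are lognormal with σ² = ln(1 + CV²), so the requested CV is
the population CV exactly.

## Numerical choices and problem sizes

* Quadrature: 20 Gauss–Hermite nodes per dimension; L-BFGS-B with ftol
  1e-9 on (β, log σ²); log-variance bounds [−14, 6] with boundary flags.
* Newton mode-finding: damped steps clipped at 4 on the log scale.
* Distance matrices are symmetrised and validated to 1e-12.
* Degenerate inputs (all-zero distance matrices, single-taxon libraries,
  saturated designs) return explicit errors or flagged NaNs, never silent
  zeros.
* Validation problem sizes: calibration tests use 500 null LRT simulations
  (Gaussian LMM) and 50 count-table simulations × 6 taxa
  (Poisson-lognormal); bootstrap-coverage checks use 2,000 simulation
  repeats of the 35 × 3 design with 500-draw bootstraps; per-taxon recovery
  uses counts at the scale of an abundant taxon in a 10⁵-read library.
  These sizes keep Monte-Carlo error well below the tested tolerances.

## Known limitations

* The univariate estimators assume Gaussian metric values within hosts;
  strongly discrete metrics (low richness) violate this.
* Percentile bootstrap CIs are slightly liberal at 35 hosts (see above).
* The PLN fitter's LRT relies on the χ² reference for fixed effects; for
  very sparse taxa (most counts zero) the asymptotics degrade and the
  prevalence filters should be applied first.
* Only fish vs within-fish repeatability is decomposed; family-level
  (multi-tier) repeatability is not implemented.
* PERMANOVA interaction terms in unreplicated cells are not estimable and
  surface as zero-df terms.
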