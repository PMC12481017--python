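# Methods

This note records the statistical model behind `tmrcall`, the defaults
and why they are what they are, what the synthetic cohorts do and do not
emulate, and the numerical choices a maintainer would want written down.

## Discovery model

The unit of analysis is a transcript with a known TSS/TES. Within its
search region (body + 5 kb upstream of the TSS and 5 kb downstream of
the TES, strand-aware, clipped at the chromosome start) every CpG site
contributes one test: the pairwise-complete Spearman correlation between
its per-sample beta values and the transcript's normalized expression.
Two data-quality rules precede the test: beta values at cells covered by
fewer than `min_reads = 10` WGBS reads are masked (the read counts are
kept — region-level tests use them), and a CpG with fewer than
`min_samples = 30` complete (methylation *and* expression) pairs is left
missing. Significance uses the classical t approximation
t = ρ√((n−2)/(1−ρ²)) with n−2 degrees of freedom, two-sided, floored at
1e−300 so that |ρ| = 1 cannot produce an infinite score.

Multiple testing is corrected by Benjamini–Hochberg **within each
transcript's track**, not genome-wide. The track is the object that gets
smoothed and segmented, and a genome-wide correction would couple the
scores of unrelated transcripts; users comparing q-values across
transcripts should be aware of this scope.

Adjusted p-values become signed scores, sign(ρ)·(−log₁₀ q), and are
smoothed with a symmetric exponential moving average: the window holds
`n_flank = 10` CpGs on each side (window size 2·n_flank + 1 = 21), the
weight at CpG offset k is `smoothing_factor^|k|` with
`smoothing_factor = 0.75`, and weights are renormalized over window
members that exist and are non-missing. Edge windows are truncated, not
padded; a missing center still receives a value from its neighbours; an
all-missing window stays missing. `smoothing_factor = 0` is the
identity.

Maximal runs of consecutive CpGs whose smoothed score is ≤ log₁₀(0.05)
(negative) or ≥ −log₁₀(0.05) (positive) are grouped into regions.
"Exceeds" is inclusive: a CpG exactly at the threshold belongs to the
run. Missing smoothed values break runs — there is no evidence to
bridge across. A region's interval spans its member CpG positions
(`[first, last + 1)`), conservative rather than extended to midpoints
between flanking CpGs. Two refinement filters follow: regions with fewer
than `min_cpgs = 5` CpGs are dropped, and when a mappability track is
given, regions are kept only if every base lies in intervals with score
≥ 1.0 (`full_containment`; an `any_overlap` mode exists because the
conservative reading is a choice, not a necessity).

Transcript-level calling is retained even when isoforms of one gene
yield overlapping regions; gene-level deduplication is left to the
caller.

## Expression normalization

Raw transcript counts (reals, as pseudo-aligners emit) are normalized by
median-of-ratios: reference = per-transcript geometric mean over
samples, computed only over transcripts with strictly positive counts
everywhere; a sample's size factor is the median of its ratios to the
reference, taken in log space (this matches the reference
differential-expression implementations and equals the plain median
whenever the reference set has odd size). Size factors are then anchored
so the **median sample has factor 1**. The anchor is a pure reporting
convention — it cancels in every within-analysis ratio — but it makes
normalization exactly scale-equivariant: multiplying one non-median
sample's library by c multiplies its factor by exactly c and leaves all
normalized values unchanged, which is also the property the test suite
pins down. Spearman correlation downstream is invariant to per-sample
monotone maps across transcripts but not across samples, so
normalization is retained rather than skipped.

## Differential region methylation

For a region and two sample groups, per-sample methylated/total read
counts are summed over member CpGs. The model is beta-binomial with
group-specific means and a shared dispersion φ (parametrized so
a = μ(1−φ)/φ, b = (1−μ)(1−φ)/φ; φ is the within-sample read
correlation). Estimation is two-stage:

- **Dispersion** by within-group method of moments: the Pearson
  chi-square of each group around its own mean is matched to its exact
  first moment, which is linear in φ and accounts for the estimated
  group mean. Groups whose mean sits at 0 or 1 contribute nothing (their
  within-group variance carries no dispersion information). Estimating φ
  jointly by maximum likelihood is attractive on paper but fails in two
  ways in practice: a genuine between-group difference can be absorbed
  into an inflated common dispersion under the null, and on degenerate
  data (deterministic within-group counts) φ is unidentifiable and the
  optimizer can wander to the all-or-nothing boundary φ → 1.
- **Means** by maximum likelihood at the fixed φ: group-specific means
  (alternative) and a single common mean (null), each a 1-D Brent
  optimization on the logit scale, clamped to [1e−6, 1−1e−6].

The likelihood-ratio statistic is referred to **F(1, N−2)** (N = covered
samples) rather than χ²(1): at realistic group sizes (~10 per group) the
asymptotic χ² reference is anticonservative (empirical size ≈ 0.07 at
α = 0.05 in the null simulations below), while the F reference restores
nominal size (measured 0.044–0.051 across seeds). `reference="chi2"`
selects the asymptotic test for comparison with other tools. Calls
("hyper" = group A more methylated) are made after BH adjustment across
regions at q < 0.05 with no effect-size cutoff by default.

The promoter-definition analysis applies this test per TSS under several
fixed windows `[−upstream, +downstream)` in transcription orientation
and tabulates discordance: transcripts called hyper under one definition
and hypo under another, per-definition exclusive calls, and the
significant-call intersection matrix. No catalog of literature
definitions is hardcoded; definitions are caller-supplied configuration.

## Enrichment statistics

- **Annotation interval sets**: observed overlap in base pairs versus
  1000 permutations in which every query interval is relocated,
  length-preserved, to a uniformly random position in the universe
  (universe interval chosen proportionally to its eligible start
  positions). Shuffled intervals may overlap each other — forbidding
  that would change the null. Empirical p uses the add-one rule, so it
  is never zero.
- **Binding sites**: two-sided Pearson chi-squared (no continuity
  correction; a Yates flag exists) on the 2×2 of {query CpGs, background
  CpGs} × {in sites, not}. The background is the full search-region CpG
  set, a superset of the query; with the query a small fraction of the
  background (the realistic regime) the induced dependence is
  negligible, and the null simulations below use a ~3 % query fraction.
- **Gene sets**: one-sided (greater) Fisher exact test against a
  caller-supplied background (protein-coding genes in the intended use),
  gene sets intersected with the background first.

BH across annotations/regulators/gene sets is applied by the caller (the
CLI does it per results table).

## Synthetic cohorts

The generator emulates exactly the statistical structure the pipeline
assumes, at desk scale: per-transcript latent log-expression
z ~ Normal(μ_t, 0.8) with μ_t ~ U(log 50, log 500); log-normal library
factors (σ = 0.3) so normalization has real work to do; counts
round(exp(z)·lib); CpG positions with Poisson gaps (mean 80 bp) and a
denser TSS-proximal stretch (mean 16 bp, 20 CpGs) so smoothing windows
span realistic distances; background beta values from per-CpG
Beta(m·10, (1−m)·10) with m ~ U(0.05, 0.95); coverage per cell
negative-binomial (mean 30, size 5), giving ~7 % of cells below the
10-read mask; methylated reads binomial. Inside a planted window of 12
CpGs the beta is expit(logit(m_c) − γ·z_std + ε), ε ~ Normal(0, 1), with
mid-range baselines m_c ~ U(0.35, 0.65) so the logistic coupling is not
saturated. γ is calibrated by bisection so the realized Spearman
magnitude between the **window-mean** observed beta and expression hits
the requested coupling (default 0.8); the window mean is the quantity
the method ultimately reports for a region, and per-CpG calibration
would push window-level correlations to ≈0.96. The reference cohort is
120 samples × 100 transcripts × 60 CpGs with 20 planted negative windows
and four low-mappability decoy intervals over signal-free transcripts.

Direction is implemented by reflection: transcripts carrying positive
windows reuse the negative-coupling draws with the whole transcript's
methylated counts reflected (meth → coverage − meth). The background
beta family is symmetric under reflection, so the construction is
distributionally equivalent, and it makes a direction flip an exact
mirror — identical region boundaries with opposite sign — rather than a
statistical tendency. Mixed directions on one transcript are rejected.

What the simulation does **not** emulate: chromosome-scale genomes,
realistic CpG-island methylation architecture, allele-specific
methylation, tumour-purity mixtures, batch effects, or mappability
artefacts that *generate* spurious correlation (decoys only mark
regions as poorly mappable). Passing tests therefore demonstrate that
the implementation recovers the coupling structure it models, not that
the defaults are optimal on real cohorts.

## Numerical choices and problem sizes

- p-value floor 1e−300; BH implemented as vectorized step-up with
  NaN pass-through (missing tests neither adjusted nor counted).
- Beta-binomial optimizations: Brent on the logit scale, xtol 1e−8;
  parameters clamped to [1e−6, 1−1e−6].
- Coordinates are 0-based half-open everywhere internally; GTF is
  converted on input (1-based inclusive), BED/bedGraph pass through.
  CpG sites are identified by the position of the C; duplicate positions
  within one input file (e.g. per-strand calls) are summed.
- CAGE TSS support defaults to an exact-position, same-strand match
  (`tolerance_bp = 0`) with ≥ 10 tags; the tolerance is configurable
  because requiring support at the exact base is the strictest reading.
- Determinism: the pipeline is deterministic given inputs and config;
  all stochastic stages (simulation, shuffling, subsetting) take a seed
  or Generator, and the CLI derives per-stage seeds from one config
  seed.
- Test-suite problem sizes are chosen to finish in minutes on one CPU:
  the reference cohort above for end-to-end checks, 2000 simulated null
  regions/tables for calibration, 1000 random tracks for the smoothing
  oracle, 10⁵ permutations × 20 cases for the Spearman p check, 1000
  location shuffles for enrichment calibration, and subset sizes
  {20, 30, 60, 120} × 2 replicates for the saturation curve.

## Known limitations

- The t approximation for Spearman p-values carries an O(1/n) bias
  (≈5·10⁻³ on mid-range p at n = 30); it is the construction the method
  specifies, but exact permutation p-values would differ at that order.
- Smoothing trades boundary sharpness for noise suppression: with
  strongly significant scores the exceedance run extends a few CpGs
  beyond the true coupled window (≈3 CpGs at the reference cohort's
  score magnitudes), so region edges should be read as smoothed, not
  base-precise.
- BH within-track means q-values are not comparable across transcripts
  in the strict FDR sense.
- The beta-binomial F reference is a small-sample heuristic (exact size
  would require region-specific null simulation).
- No covariate adjustment (e.g. tumour purity) and no gene-level
  deduplication of isoform regions by default.
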