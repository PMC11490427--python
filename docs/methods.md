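# Methods

This note records the models, numerical choices and limitations behind
`meltstr`, in the order data flows through the package.

## Melt-curve model (synthetic data)

A post-PCR HRM experiment records fluorescence F(T) of an
intercalating-dye-saturated amplicon while T ramps 60→95 °C in 0.1 °C
steps (351 points, each held briefly for a reading). Duplex
dissociation releases dye, so F falls around each species' melting
temperature. The simulator models each duplex species as a two-state
logistic transition:

    F(T) = b0 + b1·(T − 60) + A · Σ_i w_i · σ((Tm_i + J − T) / s) + ε(T)

- σ is the logistic function; `s` (`transition_slope`, default
  0.30 °C) sets transition width — ~80% of a species' drop happens
  within ±1.4 s of its Tm.
- Each allele contributes one species of weight 1; a homozygote has a
  single species of weight 2 (same total product). An optional
  heteroduplex species (off by default) melts `heteroduplex_delta` °C
  below the lower allele Tm with weight `heteroduplex_weight`; real
  heterozygote HRM shows this species, and enabling it stresses the
  classifiers, but the default design matches the two-species model the
  analyses assume.
- J ~ N(0, σ_Tm²) is drawn once per sample (run-to-run thermal
  calibration error; default σ_Tm = 0.05 °C); ε is iid N(0, σ²) per
  reading (default σ = 2 fluorescence units = 0.2% of the amplitude
  A = 1000).
- The baseline (default intercept 100, slope −0.5 /°C) has constant
  dF/dT, so it cancels in normalized derivatives but sets the height
  read at the 64.95 °C pad position.

Melting temperature follows the classic length/GC dependence

    Tm = c0 + c1·gc − c2 / length,   length = flank + 4·repeats

with defaults c0 = 67.0 °C, c1 = 41.0 °C, c2 = 675 °C·bp. For the
D5S818 amplicon (flank 119 bp, gc 0.38 — calibrated placeholders, the
true values for the published primers are not on record) this puts the
panel near 78.4–78.6 °C and makes one repeat unit worth ≈ 0.1 °C —
deliberately small, because closely related genotypes producing almost
identical curves is the central difficulty of melt-based STR
genotyping. Tests that need a learnable ("well-separated") regime raise
c2 to 1850 and compensate c0 (74.3), giving ≥ 0.25 °C per repeat across
the panel at the same absolute temperatures.

Reproducibility: each sample draws from `default_rng([seed, index])`,
so datasets are bit-identical across runs and independent of generation
order.

What the simulator does *not* model: amplification-phase effects (Cq,
plateau differences), nearest-neighbour thermodynamics, salt/dye
corrections, temperature-dependent dye quenching, or inter-run baseline
drift beyond the linear term. Passing the recovery tests therefore
shows the pipeline extracts the information this generative model puts
in — it does not certify performance on real instrument data, whose
noise structure is richer.

## Derivative and feature extraction

−dF/dT is computed as finite differences at interval midpoints. On the
canonical grid the midpoints are 60.05, 60.15, …, which makes 64.95 °C
a native grid point: the pad rule needs no interpolation (non-canonical
grids fall back to linear interpolation). The raw differences are
smoothed with a Savitzky–Golay filter (window 11 points = 1.1 °C,
degree 3 by default; window 1 disables smoothing). Negative smoothed
values are kept — clipping would bias pad heights.

Peak and shoulder identification (config `PeakConfig`):

1. Resolved candidates: local maxima inside the melt window
   (default 70–90 °C) with topographic prominence ≥ ρ·(tallest
   in-window value), ρ = 0.05. The tallest candidate is the primary
   (ties go to the lower temperature); the rest are resolved shoulders.
2. Unresolved shoulders: with g the first difference of the smoothed
   derivative, a terrace on the ascending flank is an interior local
   minimum of g with g > 0 and g ≤ τ·max(g) over that flank
   (τ = 0.15); the descending flank is symmetric (local maximum,
   g < 0, |g| ≤ τ·max|g|). A terrace must additionally sit at a
   derivative height ≥ ρ·(primary height): far from the transition the
   slope hovers near zero and would satisfy the τ-test on any curve,
   noiselessly from float wiggle and pervasively under noise, without
   being a melt feature. Adjacent qualifying points merge into one
   terrace.
3. Heights are read from the smoothed derivative at the detected
   temperatures; output order is primary first, then shoulders by
   ascending temperature.

Feature vectors have exactly k observations (k = 3 for D5S818, 4 for
D18S51, matching the locus designs): surplus shoulders are dropped
keeping the tallest, deficits are padded with the (temperature, height)
pair (64.95 °C, smoothed −dF/dT at 64.95). Padding a full pair rather
than a bare height keeps the vector layout uniform; the constant pad
temperature adds no discriminative signal (see the LDA ridge below).
The terrace test's geometry is worth knowing: for a 0.7/0.3 species
mixture at slope 0.4 °C the flattening it detects first appears at
≈ 1.5 °C component separation — closer components leave the flank slope
strictly monotone and genuinely show no shoulder, while beyond
≈ 1.8 °C the second component resolves into its own local maximum.

## LDA

Textbook estimator: class means; pooled within-class covariance
Σ_W = Σ_c Σ_{i∈c}(x_i−μ_c)(x_i−μ_c)ᵀ/(n−C); discriminant
δ_c(x) = xᵀΣ⁻¹μ_c − ½μ_cᵀΣ⁻¹μ_c + ln π_c. Posteriors are
softmax(δ) — exact under the shared-covariance model. Priors default to
uniform (the published benchmark is against a 1-in-C chance rate;
empirical priors are a config option). Ties break toward the earlier
class label.

Ridge: Σ is stabilized as Σ_W + λ·diag(s), λ = 1e-6, where s_i is the
i-th diagonal entry — or, when that entry is zero up to float dust
(relative tolerance 1e-12), the mean of the informative diagonal
entries. The degenerate case is real, not hypothetical: when every
sample in a dataset pads, the pad-temperature columns are exactly
64.95 everywhere and Σ_W is singular; a ridge proportional to a zero
diagonal would add nothing, so the fallback scale is what actually
makes the solve well-posed. λ = 0 is allowed and raises an instructive
error if Σ_W is singular.

## PCA typing

Curves are normalized before PCA: smoothed −dF/dT restricted to the
melt window, min-max scaled to [0, 1]. The derivative removes additive
baselines exactly and the scaling removes per-sample amplitude, leaving
melt-peak shape only. Loadings are the top-m eigenvectors of the
sample covariance (computed by SVD of the centered matrix, n−1
divisor), with each loading's largest-magnitude entry forced positive
for reproducibility. m defaults to 2.

Class Gaussians live in score space: per-class mean, pooled covariance.
The pooled covariance uses the MLE divisor n rather than n−C, so
duplicating the training set (or re-running identical standards)
leaves the fitted Gaussians bit-identical — with 7–10 standards per
class the bias difference is immaterial, and the invariance is worth
having. Pooling across classes (per-class covariance is a config
option) reflects that 7–10 standards cannot support stable per-class
full covariances in m ≥ 2 dimensions. A tiny relative jitter
(1e-12·trace/m) guards against perfectly collinear score clouds.

An unknown is assigned argmax of the class posteriors (uniform priors,
shared covariance, so posteriors reduce to softmax of −d²/2 with d the
Mahalanobis distance); when d² to the *best* class exceeds the χ²(m)
quantile q (default 0.999) the sample is returned `UNCLASSIFIED` — the
"acceptable variability" cutoff. Unlike instrument-bound cluster
software, the fitted model serializes to JSON and types unknowns run at
any later time.

## Evaluation

Confusion matrices are rows = known, columns = predicted, labels in
lexicographic (allele_a, allele_b) order. Both micro (pooled counts)
and macro (mean of per-row recalls) subset accuracies are first-class
because published homozygous/heterozygous splits use both conventions,
depending on the table; every consumer states its mode. Per-class
recall of an empty row is reported as absent (`None`), not 0. The
near-miss predicate holds when two genotypes share exactly one allele
value and the remaining alleles differ by exactly one repeat, with the
shared-allele matching maximized over the two pairings; it is symmetric
and false on identical genotypes.

Geno-group evaluation supports two protocols, because "evaluate the
grouping the other way around" is ambiguous in practice: **collapse**
sums the cells of the genotype-level matrix into group cells (grand
total conserved; accuracy can only rise, since within-group errors
become hits and nothing leaves the diagonal), and **retrain** refits
the classifier on group labels (accuracy can move either way). The
eleven published grouping options for the two loci ship as named
fixtures. The published *retrained* group accuracies cannot be
reproduced without the original raw curves; the collapse-protocol
numbers derivable from the printed matrices (e.g. 147/185 ≈ 79.5% for
the D5S818 LDA matrix under option A) are computed and tested instead.

One published inconsistency is handled explicitly: the D5S818 PCA
table's printed overall rate (23.77%) differs in the second decimal
from trace/total of its printed cells (49/206 = 23.79%), so that table
is used only for its macro homozygous/heterozygous rates
(39.58%/20.18%), which reconcile exactly.

## Problem sizes and tolerances

The recovery checks use the full published training design (7–10 → 8
standards per genotype) with 504 held-out unknowns for the low-noise
regime, 700 for the shuffled-label control (averaged over 10 shuffles —
a single shuffle of 56 labels retains accidental alignment and its
accuracy varies by several points around the 1/7 expectation), and 210
for the 20×-noise control. Table statistics are asserted at the printed
2-decimal precision; eigenvalue and density oracles at 1e-8 and
1e-10; peak positions at 0.15 °C (1.5 grid steps) for component
separations ≥ 6 s. The whole suite runs in a few seconds on one CPU.

## Known limitations

- The shoulder detector is a fully specified stand-in for what the
  original analyses did by visual inspection; its thresholds (ρ, τ)
  are defaults, not fits to real curves.
- Amplicon flank lengths and GC fractions for the published primer
  pairs are calibrated placeholders (see above).
- PCA typing here is *not* byte- or cluster-compatible with the
  proprietary software it mirrors; its preprocessing and component
  choices are unpublished.
- Multi-locus joint genotyping, mixtures, and degraded-sample effects
  are out of scope.
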