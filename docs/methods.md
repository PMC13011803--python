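# Methods

This note documents the models, conventions and design choices behind
`domlink`, in the spirit of a statistical methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Formula chemistry

Formulae are neutral CHNOSP compositions with C ≥ 1 and H ≥ 1. Masses are
neutral monoisotopic sums (C 12 exactly, H 1.0078250319, N 14.0030740052,
O 15.9949146221, S 31.97207069, P 30.97376151 Da); conversion to the
[M−H]⁻ ion (−1.00728 Da) is available but not used by the pipeline, which
never needs ionized masses.

The modified aromaticity index is

    AI_mod = (1 + C − O/2 − S − (N+H)/2) / (C − O/2 − S − N − P).

Negative raw values and non-positive denominators are reported as 0 (the
standard reading: no aromatic character). Raw values above 1 occur for
extreme H-poor compositions (e.g. C₂H₁ gives 1.25); these are reported as
1 so the index is always a fraction in [0, 1]. Both clamps are package
conventions, chosen so the index is comparable across any formula the
annotation accepts.

**Bioavailability** uses the H/C ≥ 1.5 rule (boundary formulae are
bioavailable); the cutoff is a keyword argument throughout.

**Compound classes** come from a rectangle scheme on the van Krevelen
plane, applied top-to-bottom with first match winning:

| class | H/C | O/C |
|---|---|---|
| lipid-like | [1.5, 2.0] | [0, 0.3] |
| protein-like | [1.5, 2.2] | (0.3, 0.55] |
| amino sugar-like | [1.5, 2.2] | (0.55, 0.7] |
| carbohydrate-like | [1.5, 2.4] | (0.7, 1.2] |
| unsaturated hydrocarbon-like | [0.7, 1.5) | [0, 0.1] |
| lignin-like | [0.7, 1.5) | (0.1, 0.67] |
| tannin-like | [0.5, 1.5) | (0.67, 0.97] |
| condensed aromatic-like | [0.2, 0.7) | [0, 0.67] |

Anything else is `unassigned`. Published rectangle schemes differ in their
exact boundaries; this table is a documented, config-overridable stand-in
that reproduces the class names standard in DOM work with unambiguous,
testable edges.

**Replicate-presence filter.** Within each (source, day) group of
replicate bottles, a formula is kept only if its intensity is positive in
at least `min_reps` (default 2) replicates; otherwise it is zeroed for
that group, and the matrix is re-normalized. "Present" means intensity
> 0 — the matrix is already peak-level, so no separate detection-limit
model is applied here. Groups smaller than `min_reps` (single control
bottles) pass through unfiltered with a warning.

## Distance-based ecology

All five analyses are implemented directly on numpy linear algebra; the
test suite cross-checks them against scikit-bio, scipy and closed-form
oracles.

* **PCoA**: eigendecomposition of the Gower-centered −D²/2. Negative
  eigenvalues (expected for Bray–Curtis) are counted, warned about, and
  excluded from the proportion-explained denominator; no Lingoes/Cailliez
  correction is applied, matching the common default behavior of
  ecological software.
* **PERMANOVA**: McArdle–Anderson trace form. The model matrix is an
  intercept plus dummy-coded factors and raw numeric columns; a pivoted QR
  detects aliased columns and names them in the error. Permutations
  shuffle sample labels (rows/columns of G); p-values use the add-one
  convention (1 + #{F_perm ≥ F_obs})/(1 + n_perm), so the smallest
  attainable p is 1/(n_perm+1). A `strata` option restricts permutations
  within groups for repeated-measures designs but defaults off. If the
  total inertia is numerically zero (all samples identical) the test
  returns F = 0, p = 1 rather than 0/0.
* **envfit**: each variable is regressed on the first two (configurable)
  axis scores; the arrow is the unit coefficient vector, r² the regression
  R², p from permuting the variable's rows. Zero-variance variables are
  flagged with r² = 0, p = 1.
* **Procrustes/PROTEST**: symmetric scaling — both configurations
  centered and scaled to unit sum of squares, optimal rotation from the
  SVD of X'Y, M² = 1 − (Σ singular values)², so M² ∈ [0, 1] and
  PROTEST r = √(1 − M²). The narrower configuration is zero-padded to the
  wider one's axis count. Significance permutes the row order of the
  second configuration.
* **dbRDA** shares the PERMANOVA engine with numeric predictors; R² is
  the constrained inertia fraction tr(HGH)/tr(G). When the pipeline asks
  "how much of the community structure does DOM composition explain", the
  predictors are the DOM PCoA axes cumulatively covering ≥ 90% of the
  positive inertia (the threshold is a config knob) — a parameterization
  choice, since distance-based ordinations admit many.

## Correlation screens

**Spearman** is computed as the Pearson correlation of midranks
(scipy `rankdata`), vectorized over formula profiles. Constant series are
undefined and excluded from downstream pooling, never NaN-propagated.

**Eligibility.** A formula enters a source's screens only if present in
≥ 2 replicates at *every* sampling day of that source. Control bottles are
excluded from all screens but retained in the chemistry outputs.

**Pooling.** Correlations use all replicate samples of a source (3
replicates × 4 days = 12 points, day or species abundance as the
covariate) rather than replicate means: midrank Spearman handles the
repeated covariate values naturally, and pooling preserves the replicate-
level noise structure the thresholds must contend with. A replicate-mean
mode is not provided.

**Percentile thresholds** are always realized from the data: the cutoff is
the k-th most extreme order statistic of the pooled distribution,
k = ⌈f·n⌉, ties at the cutoff all kept. Two-sided selection works on |ρ|
and splits flags by sign; one-sided negative selection takes the lower
tail of the signed distribution (so, at f = 0.025, the cutoff is the 2.5%
quantile of all correlations, not of negatives only). Published analyses
of this kind report fixed cutoffs (−0.706, −0.806, 0.750) that were
themselves realized percentiles of the data in hand; recomputing them
keeps the screen calibrated on any dataset.

**Exact multinomial test.** p = Σ P(outcome) over all outcome vectors
whose multinomial probability is ≤ that of the observed vector (the
small-probability ordering). Full enumeration of the outcome lattice when
the total count is ≤ `exact_limit` (default 60); above that, a seeded
Monte-Carlo estimate with ≥ 10⁵ draws, flagged in the result and bounded
below by 1/n_draws. For the three-category case the enumeration is
O(n²) and remains practical far beyond the default limit.

**Class enrichment.** The selection null is three-category: a formula is
selected-positive with probability f/2, selected-negative with f/2, and
unselected with 1 − f, where f is the screen's top fraction. This
structure is what makes the multinomial + post hoc binomial pairing
coherent: if the multinomial p is below α (0.05), one-sided binomial
tests of each direction's count against Binomial(n_class, f/2) decide the
verdict — preferentially consumed (negative side), produced (positive
side), or both. A two-category variant (positives vs negatives among
selected only) is available via `categories="two"`. No multiple-testing
correction is applied across classes or sources by default, matching how
raw P < .05 decisions are usually reported for these screens.

**Species differences.** The question "do species differ in the
probability that a formula is selected as used?" is answered by a
stratified permutation test instead of a binomial mixed model: the
statistic is the between-species variance of cell-averaged use
proportions, and the null shuffles species labels within each
(source, class) stratum, which preserves every cell's denominator
exactly. Pairwise contrasts use |mean difference| under the same
permutations. This is a substitution for, not an equivalent of, a GLMM —
it tests exchangeability of species within cells, without random-effect
shrinkage.

**Joint depletion** intersects the species screen with the
declining-with-time screen (each at its own one-sided 2.5% threshold).
The resulting (species, formula, source) triples are the screen's
predicted consumption links, scored against simulated ground truth by
precision and recall over consume-kind links.

## The synthetic microcosm

The simulator generates the study design the pipeline expects: 7 DOM
sources in three lability groups (1 fresh labile, 3 worked labile, 3
recalcitrant), 3 replicate bottles plus 1 bacteria-free control per
source, sampling days {1, 4, 7, 14}, 6 species.

**Library.** Each source carries 500 formulae: 60% from a core shared by
all sources, 40% source-unique, sampled so every compound class is
populated (rejection sampling of integer element counts into target
rectangles; C ~ uniform 8–40). Unique formulae follow group-specific
class mixtures (labile sources richer in bioavailable classes,
recalcitrant sources in aromatic ones), and initial intensities are
lognormal (σ = 1) scaled by group-specific class weights.

**Planted links.** One consumer per source, 10 consumed formulae each,
concentrated in one compound class per source: the specialist eats
protein-like formulae of the fresh labile source only (all bioavailable);
the broad generalist eats a different bioavailable class on each of the
three worked labile sources (30 links — the broadest niche); three other
generalists each eat lipid- or tannin-like formulae on one recalcitrant
source; the last generalist gets a small secondary niche (3 links) on the
final recalcitrant source. Each consumer also produces 3 formulae in a
less bioavailable class (lignin-like on labile groups, condensed
aromatic-like on recalcitrant). Per-link rates are the configured rate
× uniform(0.7, 1.3). Consumed formulae start at 2.5× the base lognormal
intensity — they are abundant, well-detected peaks — replacing (not
stacking with) the class weight so the consumed mass share is comparable
(~4%) on every source.

**Dynamics.** Discrete multiplicative updates in 1-day steps (finer than
the sampling gaps, so update factors stay in (0, 1] at realistic rates and
consumed trajectories are strictly monotone):

    flux_s   = Σ_i rate_i · x_i            (over s's resources, x = relative intensity)
    b_s     ← b_s · (1 + yield · flux_s)   (replicator-style growth)
    X_i     ← X_i · (1 − Σ_s rate_i · a_s) · (1 + Σ_s prate_i · a_s)

with a the species' relative abundances; factors are clipped at 0 with a
warning if rates are set large enough to go negative. Each replicate
bottle runs its own dynamics from its own inoculum: starting abundances
are jittered with CV 0.1 (communities are assembled at approximately equal
biomass, not equal cells), while the DOM profile is shared (one media
batch). An optional efficiency multiplier can penalize the broad
generalist's yield; it defaults to 1.

**Measurement.** Per sample: mean-preserving lognormal noise
(σ² = ln(1 + CV²), μ = −σ²/2, CV default 0.05) on every entry, then
detection-limit dropout — only peaks below the sample's median positive
intensity can drop, at twice the nominal rate (default overall rate
0.05) — then closure to 1. Uniform dropout would silence abundant peaks,
which real instruments essentially never do, and was rejected for that
reason. Controls carry the initial DOM profile with measurement noise
only and appear only in the intensity table (replicate 0, flagged).

**What the simulator does and does not emulate.** It produces monotone
planted signals with controllable noise, compositional closure in both
matrices, replicate-level dropout for the presence filter to act on, and
bottle-level demographic variation. It does not model sequencing depth or
16S copy number, chemostat mechanics, cross-feeding chains, instrument
drift, or correlated measurement error. Passing recovery tests therefore
demonstrates that the screens detect monotone consumption signatures at
realistic noise — not that they would be unbiased on real amplicon/FT-MS
data, where library-size and copy-number effects add structure the
simulator deliberately omits.

## Behavior of the screens under closure (known limitations)

Compositional closure has two consequences the tests make explicit:

1. **Closure-risers.** When consumed mass leaves a source, every
   unconsumed formula rises in relative intensity. At realistic noise
   these risers can exceed the positive selection threshold and produce
   "preferentially produced" verdicts in classes with no planted
   production — the same relative-abundance effect that makes less
   bioavailable compounds appear to increase when bioavailable ones are
   consumed. This is a property of the method on compositional data, not
   a defect; the recovery tests assert that all planted consumed classes
   are flagged, and that type-I error is controlled on a no-links null,
   rather than asserting zero flags in unplanted classes under planted
   consumption.
2. **The mean-use-proportion ranking is noise-dominated.** The 2.5%
   species screen always selects a fixed share of the correlation pool;
   with realistic link densities most selections are riser × decliner
   pairs, and a species gains more mean proportion from declining on a
   source (and anticorrelating with its risers) than from genuinely
   consuming ten formulae there. The broadest consumer therefore does
   *not* reliably top the per-cell mean-proportion ranking. It does,
   robustly, top the summed joint-depletion counts, because the
   intersection with declining-over-time formulae removes the riser
   pairs; the qualitative replica test asserts the ranking at that level.
3. **Sub-default noise is not benign.** Recall of planted links is
   monotone non-increasing in measurement noise from the default upward
   (0.05 → 0.2), but *decreasing* noise below the default also hurts:
   near zero noise every closure-riser and every relative decliner
   becomes perfectly rank-correlated, the percentile tails fill with
   them (ties at the cutoff are all kept), and true links are crowded
   out. Percentile screens on compositional data need noise of the same
   order as the closure-induced trends to separate mechanism from
   artifact.

## Numerical conventions

* Permutation p-values: add-one convention everywhere; every stochastic
  routine takes a seed, records it in its result object, and the pipeline
  derives per-stage seeds from one root seed (CRC-keyed SeedSequence).
* Comparisons against permuted statistics use a 1e-12 slack so exact ties
  count as "at least as extreme".
* PCoA eigenvalue tolerance: relative 1e-8 of the leading eigenvalue.
* CSV output: stable column order, floats at 10 significant digits; the
  long intensity table omits zero entries.
* The calibration studies use 3 sources × 300 formulae with no planted
  links (null) and the full default design (recovery); enrichment type-I
  error grows mildly with library size because closure and shared dropout
  correlate formulae within a source, violating the multinomial's
  independence assumption — at 300 formulae the measured rate is close to
  nominal.
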