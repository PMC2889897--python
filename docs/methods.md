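# Methods

This note records the models, conventions and design choices behind the
pipeline, in the order the stages run.

## Synthetic cohort model

The generator emulates a two-color-free microarray screen of blood-cell
miRNA expression. Per feature *f* a baseline log2 intensity
μ_f ~ Uniform(5, 14) is drawn; each spot (feature × sample × replicate)
measures

    intensity = 2^(μ_f + effect_f·[sample is melanoma] + batch_f·[sample in validation arm] + ε) + background

with replicate noise ε ~ N(0, `replicate_sd`), a feature-wise validation-arm
offset batch_f ~ N(0, `batch_shift_sd`), and an additive background draw
N(`background_mean`, `background_sd`) clipped at 0 and recorded alongside
the signal (mirroring an image-analysis background estimate). Defaults and
their reasoning:

| parameter | default | why |
|---|---|---|
| n_features / samples / replicates | 866; 20 C + 24 M + 11 N; 7 | the screening design being emulated |
| n_planted, frac_down | 51, 21/51 | the observed marker count and direction split |
| effect_range (log2) | (1, 3) | 2–8-fold deregulation in both directions |
| replicate_sd (log2) | 0.25 | moderate spot noise; the median over 7 replicates leaves ~0.12 log2 units of sample-level noise |
| background_mean / sd | 50 / 15 | small relative to expressed features (≥ 2^7), dominant below the floor |
| detection_floor_frac | 0.15 | share of probes with both group medians < 100 (background-level features) |
| batch_shift_sd (log2) | 0.2 | makes the test/validation fold-quotient correlation high but < 1 |

Two structural choices matter:

- **Planted markers live inside the dynamic range.** A planted feature is
  drawn so that both its control and its shifted melanoma mean stay within
  [2^7, 2^14]. Below 2^7 a marker is indistinguishable from the detection
  floor and would be discarded by the median-≥100 filter no matter how large
  its effect; above the ceiling the effect would saturate a real scanner —
  and, numerically, features pushed past the top of the common distribution
  inflate the upper reference quantiles of quantile normalization and
  corrupt the fold quotients of *unrelated* high-intensity features.
- **The qPCR model is the minimal ΔΔCt-consistent one:**
  Ct = a − log2(abundance) + N(0, `ct_sd`) with a shared per-miRNA intercept
  a ~ Uniform(22, 30) and a constant-abundance endogenous control (RNU48
  role). Case-group Ct shifts by −(planted log2 effect).

What the generator does **not** emulate: probe-sequence effects and
cross-hybridization, intensity-dependent (heteroscedastic) noise,
correlated miRNA co-regulation, sample covariates (age, sex), or scanner
saturation. Passing tests therefore show the *chain of computations* is
correct and leak-free under the assumed noise model — not that the specific
published miRNAs would be recovered from new blood samples.

## Preprocessing

Background is subtracted per replicate spot before the median over the
seven replicates (matching the stated order of operations); the median is
clamped at zero because downstream fold quotients and the intensity filter
assume non-negative values. Quantile normalization maps each column's ranks
onto the across-column mean of the sorted columns; ties within a column
receive the mean of the tied reference values, which makes the operation
deterministic and idempotent. Single-column input is refused (nothing to
normalize across).

## Single-marker statistics

- **t-test**: Welch (unequal variances) by default, switchable to Student;
  two groups that are both constant and equal give p = 1.
- **WMW**: exact enumeration when both groups have ≤ 12 observations and no
  ties, otherwise the tie-corrected normal approximation.
- **Moderated t**: per-feature two-group linear model; the prior
  (d₀, s₀²) is moment-matched on log residual variances through
  digamma/trigamma identities (trigamma inverted by Newton iteration).
  When the observed spread of log variances does not exceed the sampling
  spread, d₀ = ∞ and every feature is tested against the common prior
  variance. Total df is capped at the summed residual df across features.
  d₀ = 0 recovers the ordinary equal-variance t exactly (tested), and the
  implementation reproduces an independent empirical-Bayes linear-model
  implementation to ~1e-12 on a frozen heteroscedastic fixture.
- **AUC** is computed as the normalized Mann-Whitney U (ties count half) and
  reported symmetrized, max(AUC, 1−AUC), so strong down-regulation also
  scores near 1 — the convention of the published marker table.
- **Filters**: a marker is kept iff all three BH-adjusted p-values are
  < 0.001, the fold quotient is ≥ 2 or ≤ 0.5 (boundaries inclusive), and
  max(median_case, median_control) ≥ 100. The intensity rule excludes a
  feature only when *both* group medians are below 100: the published table
  contains markers with one group median far below 100 (e.g. a normal
  median of 2 with fold 53), so the one-sided reading would contradict it.
  A zero control median flags the feature (NaN fold) rather than silently
  dropping it.
- Reporting rounds fold changes to one decimal (integers from 10 up) and
  AUC to two decimals, matching the published formatting. Rounding is
  half-up, not banker's.

## Unsupervised structure

Samples are clustered on the unscaled normalized intensities of the top-50
variance features (no z-scoring, since none is stated for the reference
analysis; a `scale_features` switch exists). Complete linkage with
Euclidean distance; the two-cluster cut is crossed with disease status
(melanoma test and validation arms pooled) and tested by two-tailed
Fisher's exact test using the point-probability rule. A perfect 20/35
split gives p = 1/C(55,20) ≈ 2.0×10⁻¹⁵ — the hypergeometric value, which
the tests target. PCA centers but does not scale features; component signs
are fixed by forcing the largest-magnitude loading positive. Trees export
to Newick with merge heights as branch lengths.

## Signature classification

Stratified fold assignment (the 20/35 class imbalance makes unstratified
10-fold splits risk single-class test folds). Inside every fold, features
are ranked by t-test p-value on the training split only and the top-*s*
kept, for *s* over a log-spaced grid 1, 2, 4, …, 866 by default (the full
1..866 sweep is available via `subset_sizes`). The kernel/cost winner is
chosen per fold by a nested stratified CV on the training split — the only
reading of grid evaluation that cannot leak test information. Features are
standardized inside each fit (scaler fitted on training data only), the
convention of the reference SVM implementation and necessary because raw
intensities span orders of magnitude. 95% CIs are the 2.5/97.5 percentiles
of the repetition means. The best subset size maximizes mean accuracy
(smallest s on ties); the winning signature is the best-s features with the
highest selection frequency across folds. Permutation tests shuffle the
group labels (class counts preserved) and re-run the identical machinery;
each permutation reports its rates at its own best subset size, matching
how the true-label result is summarized. Per-sample scores are
log(P(melanoma)/P(healthy)) from a sigmoid-calibrated SVM; a score of
exactly 0 is called healthy by convention.

A deliberate leakage diagnostic (`rank_on_full_data=True`) ranks features
once on all samples before splitting; on a null cohort it inflates accuracy
beyond the exact binomial 99% band around the majority-class rate, while
the honest per-fold ranking stays inside it — a regression test that the
default path is leak-free.

## Concordance

Test-arm and validation-arm fold quotients (each arm's medians over the
shared control medians) are correlated on the **log** scale, keeping
features whose median intensity reaches 50 in at least one arm. Each
`FoldQuotientSet` carries its own medians so the either-arm retention rule
is applied when two sets are compared (a single arm cannot apply it alone).
The microarray-vs-qPCR comparison instead uses the **linear** fold-change
scale: recomputing the correlation of the published 13 fold-change pairs on
the linear scale reproduces the printed 0.93 (the log scale does not), so
the two operations deliberately use different scales, each matching its
printed source.

## Problem sizes and numerical conventions

The shipped drivers and the acceptance script use desk-scale sizes chosen
as the package's defaults: 10 CV repetitions (of the 100-repetition
design), the log-spaced subset grid, 10 permutations with a fixed 16-marker
subset, and 20 seeded cohorts for recovery statistics. All randomness
flows from a single integer seed through `SeedSequence`-derived child
seeds; identical config ⇒ bit-identical artifacts. Degenerate inputs
(zero-variance features, empty groups, constant fold vectors, missing Ct
values) raise typed errors or are flagged rather than silently dropped;
ties are always broken deterministically (feature id order).

## Known limitations

- The moderated-t prior estimation needs ≥ 10 features and at least one
  feature with positive residual variance.
- The permutation summary takes each permutation's best-subset rates, which
  is mildly optimistic when the subset grid is large; use a single subset
  size for calibrated null bands.
- The two-cluster Fisher p of a perfect split is the hypergeometric value
  (~2×10⁻¹⁵); reference software sometimes prints smaller values from
  numerically different tail summations.
- There is no downloader for the original deposited arrays; all shipped
  analyses run on the synthetic generator and the two packaged published
  tables, by design.
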