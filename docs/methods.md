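# Methods

## Model

A cohort of animals is induced so that each of `n` active precursors
independently and permanently commits to one fluorescent label. For a
given label carried with probability `p`, the label's cell fraction in
the progeny of animal `i` is the mean of `n` independent Bernoulli(p)
outcomes, so across animals

    Var(fraction) = p(1−p)/n,

assuming (1) the precursor number is the same in every animal of the
cohort, (2) labels are fixed at induction (no background recombination
afterwards), (3) every precursor contributes equally to the measured
population, and (4) the measured cell pool is large relative to `n`.
The estimator inverts this relation:

    n̂ = p̂(1−p̂)/σ̂²,

with `p̂` the cohort mean fraction and `σ̂` the sample SD (n−1
denominator; unbiased variance matters at cohort sizes of 5–20). The
CV form `n̂ = (1−p̂)/(p̂·CV²)` is the same estimator reparameterized;
the package computes both and tests their identity to 1e−12.

On base-10 log axes the relation is linear: `lg n̂ = lg[p̂(1−p̂)] −
2·lg σ̂`. The regression of `lg n` on `lg σ` has theoretical slope −2
and intercept `lg[p(1−p)]`; the reverse orientation (`lg σ` on `lg n`)
has slope −1/2. Both orientations are exposed under explicit names
(`fit_n_on_sigma`, `fit_sigma_on_n`) because a silent swap halves or
doubles the slope — a classic analysis bug.

Estimates are kept as real numbers; rounding is presentation-only.
When estimates are averaged across replicates, unrounded values are
averaged.

## Preprocessing pipeline

Per cohort — one (replicate, timepoint, cell_type, condition) group —
in order:

1. **Subset / chimerism renormalization.** Myeloid/T/B percentages are
   rescaled to their own sum (×100), as are CD45.1/CD45.2 percentages;
   both remove a common deflation factor from incomplete red-cell
   lysis. Idempotent; zero totals flag the sample.
2. **Marker derivation.** Three modes: `single_fp_conf` (one
   fluorophore's share of the Confetti-labeled compartment;
   Confetti% = ΣFP%), `rfp_over_rfp_plus_yfp` (RFP/(RFP+YFP), robust to
   instability of a third channel since it cancels overall labeling
   drift), and `fp_raw` (population-level FP fraction). All stored
   fractions are proportions in [0,1]; percent columns are converted at
   ingest, and series handed in on the 0–100 scale are auto-rescaled
   with a logged warning.
3. **Tukey fences.** Values outside [Q1 − k·IQR, Q3 + k·IQR] are
   removed, quartiles by linear interpolation of order statistics,
   one pass per derived quantity (Confetti% level, then the final
   marker fraction) — not iterated to convergence, which over-trims
   small cohorts. **Default k = 3.0** (Tukey's "far out" fence): on
   clean binomially dispersed cohorts of 8–22 samples, the inner
   k = 1.5 fence flags ~2–3% of legitimate points, deflating σ̂ and
   inflating n̂ by 12–26% (median) — a systematic miscalibration the
   estimator's validated accuracy cannot tolerate. The far-out fence
   leaves clean cohorts essentially untouched (median recovery within
   5–8%) while still removing gross contamination (a 0.99 fraction
   among ~0.5 values is far outside either fence). `tukey_k` is
   configurable for users who want the aggressive inner fence.
4. **Minimum-recorded-event exclusion loop.** An estimate above the
   smallest recorded event count among contributing samples is beyond
   that sample's counting resolution. The loop drops the
   minimum-event sample (ties broken lexicographically by sample id,
   making the pipeline invariant to row order), re-estimates, and
   repeats until n̂ ≤ min(events) or the cohort would fall below
   `min_group_size`; in the latter case the group is flagged
   `no-valid-estimate` rather than reported.
5. **Labeling-efficiency normalization** (optional). Totals are
   `n̂ / labeling_fraction`, using the cohort mean of the marker-set
   fraction measured in the same gated population at the analysis
   timepoint (e.g. mean Confetti% for `single_fp_conf`, mean
   (RFP+YFP)% for the ratio mode) as the efficiency proxy. Measuring
   efficiency at induction instead is supported by passing the value
   explicitly to `normalize_to_total`.

`min_group_size` defaults to 5: the bootstrap sample-size analysis
(below) shows the relative error of n̂ roughly quadrupling from cohort
size 5 down to 2, with only marginal gains beyond 5. No estimate is
reported from fewer than 5 samples. Every excluded sample carries
exactly one machine-readable reason; retained + excluded always equals
the input count.

## Simulators

The generators produce the statistical structure of the real assay and
serve as oracles for the whole chain:

- **fixed_n_cohort** — per animal, multinomial allocation of `n`
  precursors over labeled channels (scaled by `labeling_efficiency`)
  plus an unlabeled slot; fractions are channel count / n.
- **poisson_seeded_cohort** — per-recipient precursor numbers
  `n_i ~ Poisson(λ)` (transplant seeding); `n_i = 0` animals are
  emitted flagged `no-precursors`, not dropped, so attrition is
  visible for survival-rate corrections.
- **two_color_culture** — wells seeded with known cell numbers,
  per-cell binomial survival, founder color binomial at the mix
  fraction, neutral expansion (final fraction = founder fraction; the
  two-color validation established no competitive growth advantage).
  A `growth_generations` option adds drift-style per-generation
  binomial resampling with population doubling; off by default.
- **multispectral_cohort** — ≥3 channels with partial labeling, for
  cross-channel concordance checks.

Measurement noise is multinomial subsampling of `recorded_events` flow
events from the animal's true composition — counting `E` gated events
is a multinomial draw; the paper-level analysis quantifies the event
requirement, and this is the minimal law consistent with it.
`recorded_events=None` disables noise (the schema then carries a 1e12
sentinel so the event-exclusion loop never triggers). Fixed seeds give
byte-identical tables.

What the generators do **not** emulate: clonal drift after induction,
unequal clone output, niche geometry, label toxicity, antibody
spillover/compensation error, and non-multinomial cytometer artifacts.
Passing recovery tests therefore demonstrates correctness of the
estimator and pipeline under the model's own assumptions, not
robustness to every failure mode of real data.

Default conditions mirror the validation designs: 20 animals per
cohort (the real replicates span 8–22), channel probability 0.5
(two-channel), 10⁵ recorded events where noise matters, precursor
sweeps over 10–10⁵ (the biologically attainable range: ~1.4×10⁵
non-HSC LSK and ~5×10³ active HSCs in an adult mouse), and three
replicate cohorts per decade for calibration fits.

## Known operating range

With `E` recorded events the measured variance is ≈ p(1−p)(1/n + 1/E),
so the counting-noise floor dominates once `n` approaches `E`: at
E = 10⁵ the measured SD detaches from sqrt(p(1−p)/n) around n ≥ 10⁶
and plateaus — 10⁵ is the practical upper measurement limit at that
event depth. Below ~10 precursors, Poisson seeding breaks one-to-one
calibration: the estimator converges to 1/E[1/n | n>0], e.g. ≈2.0 at
λ = 2.5 (−20%), while λ ≥ 10 cohorts are essentially unbiased. Both
regimes are asserted by the test suite.

## Resampling (sample-size curves)

For each candidate cohort size `s`, the pooled observed fractions are
resampled with replacement `n_boot` times, n̂ estimated per resample,
and relative error reported as SD(n̂)/mean(n̂). Degenerate resamples
(all values tied, or mean at 0/1 — unavoidable at sizes 2–3) are
skipped and counted, never imputed; sizes with >50% degenerate
resamples are flagged unreliable. Caveat: because n̂ ∝ 1/σ̂² and σ̂²
is chi-square-like, SD/mean of the bootstrap distribution has divergent
moments at sizes ≤5 in the continuous limit; the reported values are
finite only through the discreteness of the pool, so curves from
different pools are comparable in shape (the sharp drop to size ~5),
not in absolute size-2 magnitude.

## Permutation inference

Estimates arrive a few per condition with no credible distributional
model. The paired test enumerates all 2^k sign flips of per-replicate
differences; the unpaired test all C(n1+n2, n1) relabelings (Monte
Carlo with the identity arrangement counted once the arrangement count
exceeds 10⁶; p can never be 0). The default direction is one-sided in
the observed direction, making the attainable minima exactly 1/2^k
(0.125 at k=3, 0.03125 at k=5) — with so few replicates, a p-value at
its attainable floor is itself informative even when it misses the
usual α. A two-sided option compares absolute statistics. Tie counting
uses a 1e−12 relative tolerance so floating-point noise cannot drop
tied arrangements.

Calibration lines are compared by standard ANCOVA F-tests: equal
slopes from the interaction term of the full model, equal intercepts
from the group term of the common-slope model — matching the expected
pattern that channels with different mean labeling share the −2 slope
but differ in intercept.

## Numerical choices and degenerate inputs

- All-identical fractions are detected by exact equality (the SD of
  identical floats can carry a ~1e−17 rounding residue) and raise an
  infinite-estimate error: the precursor number is beyond measurable
  range, not a number.
- Mean fraction at 0 or 1 raises a degenerate-labeling error.
- Log-linear fits require ≥3 strictly positive points; slope CIs use
  the t distribution with n−2 degrees of freedom.
- Flagged results serialize with an empty `n_hat`, never 0; floats
  round-trip CSV at 12 significant digits.

## Problem sizes used by the test and acceptance runs

The recovery suite uses 200 cohorts × 20 animals per decade over
10–10⁵; the calibration sweep 3 cohorts per decade; permutation
enumeration up to 2¹⁰; type-I calibration 2000 null tests; bootstrap
curves 2000 resamples. These sizes make the Monte-Carlo standard
errors comfortably smaller than every asserted tolerance while keeping
the default run quick on a single CPU.

## Limitations

- No confidence interval is attached to a single-cohort n̂ beyond the
  replicate-level dispersion the bootstrap quantifies.
- The labeling-efficiency proxy (mature-cell label fraction) assumes
  labeling is unbiased with respect to precursor output.
- Barcode/count-based estimation, FCS gating, compensation and
  batch-effect correction are out of scope.
- The unpaired attainable-minimum p is 1/C(n1+n2, n1) under standard
  relabeling enumeration (1/20 at 3 vs 3, 1/252 at 5 vs 5); other
  enumeration conventions yield different minima.
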