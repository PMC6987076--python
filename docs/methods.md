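# Methods

## Model and decision rules

**Ordinal encoding.** A window of `D` values spaced `τ` apart is encoded
by the permutation `π = (r_0, …, r_{D−1})` sorting it increasingly
(`x_{s+r_0} ≤ … ≤ x_{s+r_{D−1}}`). We use the *index* convention — `π[k]`
is the position of the k-th smallest value. The literature also uses the
*rank* convention (the inverse permutation), under which the reversal
partner of a pattern is its reversed tuple rather than the elementwise
complement `r → D−1−r` used here. The two conventions relabel patterns
but induce the identical partition of windows into reversal-pair classes,
so every pair-level count, test and curve in this package is
convention-independent; a property test verifies the equivalence on
random series.

**Ties.** The sort is stable: equal values are ordered by ascending time
index. This is deterministic and standard, but on heavily quantized or
constant input it manufactures spurious `(0,1,2)` patterns; such series
are flagged *degenerate* (single observed pattern arising from tied
neighbours) and excluded from cohort aggregation with a warning. An
optional `tie_rule="jitter"` adds seeded uniform noise at 1e−9 of the
signal SD before encoding.

**Per-series test.** For each of the `D!/2` reversal pairs with counts
`(n_a, n_b)`, the exact two-sided binomial p-value of `n_a` out of
`n_a + n_b` at null proportion 1/2 is computed in the minimum-likelihood
sense (for a symmetric null this equals doubling the smaller tail, capped
at 1; cross-checked against `scipy.stats.binomtest`). The series is
irreversible when *any* pair rejects at `α` (default 0.01). No
multiplicity correction is applied by default — this matches the
operational description of the method — but `correction="bonferroni"`
(level `α/3` at `D = 3`) is available. Pairs that never occur are
skipped: absence is no evidence of asymmetry.

**Scale scan.** A series is irreversible *at scale n* when at least
`threshold = 90%` of all overlapping length-`n` sub-windows reject at
`α = 0.01`. The scan uses cumulative pattern-pair counts plus cached
per-`n` binomial critical values, so it costs O(N) per scale and is
exactly equivalent to running the per-series test on every sub-window (a
unit test enforces this equivalence against the naive loop).
`sub_stride > 1` subsamples sub-window starts as a documented
approximation. The default window-length grid is 25 log-spaced values
from 50 samples to the shorter of the series and 100 s of signal. Units
(one channel of one recording) shorter than `n` are excluded from that
scale's denominator rather than padded — padding would re-introduce the
length confound the scale scan exists to remove.

**Cohort curves and comparisons.** The cohort scale curve is the fraction
of units irreversible at each `n`. Two cohorts are compared by, for each
grid value `x` (step 0.01): finding the smallest `n` at which the
*reference* fraction reaches `x`, reading the *comparison* fraction `y`
at that same `n`, and testing equality with the exact two-sided binomial
test of the comparison cohort's irreversible-unit count `k` out of `m`
against null proportion `f_ref(n)` (reported as log10 p, floored at
1e−300). Conditioning on the reference as the null proportion is one
defensible reading of "a binomial test, testing if both values are
equal"; pooling both cohorts would be the main alternative and differs
only in borderline cases. Unattained `x` values are omitted.

**Topography.** Per channel: the fraction of recordings irreversible at
each scale, averaged over the whole grid — one scalar per electrode
summarising all probed time scales. Difference maps are
patients − controls; positive = higher irreversibility in patients.

**Surrogates.** IAAFT alternates imposing the original Fourier amplitude
spectrum and restoring the original value multiset by rank remapping,
from a random-shuffle start, until the relative L2 spectrum discrepancy
is ≤ 1e−4 or 100 iterations (both standard practice; the amplitude step
runs last, so the value multiset is exact). The surrogate ensemble
analysis replaces every unit by an independent surrogate (per-unit
substreams of one master seed), recomputes the cohort curve, and repeats
M = 20 times (M unreported in the source protocol; 20 gives a stable
dispersion estimate), yielding the mean surrogate curve and its per-scale
SD. The per-series empirical test uses the rank formula
`p = (1 + #{surrogate ≤ observed}) / (M+1)` with the minimum per-pair
p-value as statistic (mirroring the any-pair rule); note the smallest
attainable p is `1/(M+1)`, so rejecting at `α = 0.01` needs `M ≥ 199`
surrogates. Irreversibility significant against shuffles (equivalently,
the analytic binomial test) but not against IAAFT is *weak*
(attributable to linear autocorrelation); significant against both is
*strong*.

## Synthetic data

The generator emulates the structure of resting-state EEG studies
(two groups × two conditions, 19–64 channels on 10-20/10-10 montages,
160–500 Hz, 30 s–15 min) without modelling brain biophysics. Each channel
is `w·z(logistic) + (1−w)·z(AR(1)) + σ_obs·ξ`, where `z(·)` standardizes
to zero mean/unit variance:

* **Chaotic component** — the logistic map `x_{t+1} = 4 x_t (1−x_t)`
  (burn-in 1000 steps, initial value uniform in (0,1) per seed), a
  strongly irreversible reference. Additive noise is applied at the
  *observation* stage, `y = x + σξ`: at the benchmark amplitudes
  (σ ≈ 0.63–0.72, about twice the map's own SD) dynamical noise inside
  the recursion leaves [0,1] almost surely, so those amplitudes are only
  physically meaningful as measurement noise. State and noise use
  separate seed substreams, so the orbit is σ-invariant at fixed seed.
* **Reversible background** — stationary linear Gaussian AR(1)
  (φ = 0.95 at 250 Hz, giving a 1/f-ish spectrum; no alpha peak or
  artifacts are modelled), optionally through a static monotone
  transform. Linear Gaussian processes and their static transforms are
  time-reversible, making this the null family.
* **Cohort defaults** — 14+14 subjects, 19 channels, 250 Hz, 30 s,
  mixture weights control 0.5/0.6 and patient 0.3/0.4
  (eyes-closed/eyes-open), observation noise 0.3. The weights encode the
  qualitative contrasts the pipeline is meant to resolve — patients less
  irreversible than controls, eyes-open more than eyes-closed — with
  magnitudes large enough to be recovered from a desk-scale cohort.

Because channels are i.i.d. given (group, condition), passing tests show
that the *pipeline* recovers dialled-in contrasts; they do not show that
real EEG has those contrasts, nor do they exercise spatial structure,
nonstationarity, artifacts, or volume conduction.

## Preprocessing

Band-limited variants use a *zero-phase* linear-phase FIR low-pass
(Kaiser design, 60 dB stopband, transition width 0.25·cutoff, odd-length
symmetric kernel, reflect padding trimmed to input length), then
decimation to twice the cutoff (integer factors by sample picking,
rational factors by symmetric polyphase resampling). The filter family is
the single most consequential choice here: a causal IIR filter has an
asymmetric impulse response and injects time asymmetry into the measured
quantity; a regression test verifies that filtering leaves iid-noise
detection at the nominal false-positive rate. Presets: broadband (none),
lp50 (50 Hz → 100 Hz), lp30 (30 Hz → 60 Hz). No artifact rejection or
re-referencing is performed.

## Numerical and design notes

* Rejection decisions in the scale scan use per-`n` critical values of
  the folded count `min(k, n−k)` (cached), exactly equivalent to
  thresholding the p-value but ~100× fewer CDF evaluations.
* Degenerate inputs: constant series raise in IAAFT (no phase content),
  are flagged by the per-series test, and are excluded from aggregation.
* All stochastic components (jitter, surrogates, shuffles, generators)
  accept explicit seeds or `numpy` Generators; cohort generation and the
  surrogate ensemble derive per-unit substreams from one master seed via
  `SeedSequence.spawn`, so outputs are bit-reproducible end to end.
* EDF export writes 16-bit samples in one-second records with integer
  microvolt physical bounds; quantization error is bounded by
  (range/65535) per channel and the delimited path is lossless at
  8-significant-digit formatting.
* Analysis-script problem sizes (6+6 subjects, 12-point grids, M = 8
  ensembles; 100–300 series per benchmark condition) are chosen so each
  driver completes in seconds to a few minutes on one core while leaving
  the measured effects far from their decision thresholds.
* The noisy-logistic benchmark's detection ordering across σ is assessed
  at window lengths in the 5k–40k range: at much shorter windows all
  noisy variants sit at the false-positive floor and ordering is
  meaningless (see `results/noise_masking.csv`).

## Known limitations

* Only `D = 3, τ = 1` is exercised end to end (larger `D` is supported by
  the combinatorics but untested at cohort scale, and needs far longer
  series).
* The equality test behind comparison curves conditions on the reference
  cohort (see above); its p-values are indicative, not corrected for the
  multiplicity across grid points.
* The cohort-level strength classification in the CLI (original vs
  surrogate mean ± 2 ensemble SDs at the longest scale) is a summary
  heuristic; per-series classification via `classify_strength` is exact
  but M-limited as noted.
* IAAFT preserves the spectrum only approximately (to the convergence
  tolerance); spectra with very sharp lines may converge slowly.
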