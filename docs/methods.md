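# Methods

This note documents the models and numerical choices behind `ssvepbf`:
what the synthetic generator emulates, how each processing stage is
defined, which knobs matter, and what a green test does and does not
establish.

## The statistic

For each experimental condition (tritan, luminance) the unit of analysis
is the per-subject difference map

    d_i(s, t) = env_i^{CS+}(s, t) − env_i^{CS−}(s, t)

of 7.5 Hz amplitude envelopes at sensor *s* and time *t*, computed from
acquisition-phase trial averages. Two resampling distributions are built
per cell:

* **Effect draws** (B = 2000): each draw resamples the n subjects with
  replacement and averages their maps. One subject sample is used for
  *all* cells of a draw, so the spatial/temporal correlation of the map
  survives into the draw distribution. Implemented as a (B × n)
  multiplicity-matrix product, which is memory-safe at 129-channel,
  full-epoch scale.
* **Null draws** (B = 2000): before the identical resampling step, each
  subject's condition labels are re-randomised — for a two-condition
  difference this is a sign flip with probability ½, assigned per
  subject (a subject drawn twice keeps its sign).

Evidence per cell is the all-pairs exceedance probability
p = P(effect draw > null draw), computed by sorting (strictly greater;
ties do not count), clipped to [1/(B+1), B/(B+1)] so the odds stay
finite, and reported as log10 BF10 = log10(p/(1−p)) — posterior odds
against flat prior odds of 1. The clip bounds |log10BF| at
log10(2000) ≈ 3.301. The hypothesis is directional (CS+ > CS−);
`direction="less"`/`"two_sided"` are available. No multiplicity
correction is applied; interpretation uses the Jeffreys-style bands
(0.5/1/1.5/2), and the suite's null-calibration test is the safeguard
(under a null world, < 5% of cells reach log10BF > 2; measured ≈ 0).

Properties worth knowing:

* Under the null the sign-flipped bootstrap mean has variance
  (2 − 1/n)·Σd_i²/n² — the factor 2 − 1/n is the multinomial second
  moment of the resampling multiplicities. The null is therefore
  slightly *wider* than the effect distribution, making the exceedance
  probability mildly conservative.
* The joint z-transform used for plotting draw pairs standardises both
  sets by their pooled mean/SD; it preserves ranks and leaves the
  exceedance probability exactly invariant, and the transformed null is
  generally not centred at zero.
* Transitive maps are elementwise differences of log10 Bayes factors;
  antisymmetry is exact.

Cluster summaries group sensors whose *window-averaged* log10BF strictly
exceeds a threshold (default 2) into adjacency-connected components;
singletons are reported as such, and peak latencies are constrained to
the analysis window.

## Synthetic world

The generator's defaults are the stated experimental conditions wherever
the design fixes them: 160 trials (20 habituation / 120 acquisition / 20
extinction, 30 per acquisition condition × stimulus cell, 100%
reinforcement of acquisition CS+), 500 Hz sampling, −600…3800 ms epochs,
7.5 Hz driving frequency, 4 s flicker, 3–7 s inter-trial adapter
(configurable; its realisation is not pinned by the design).
"Pseudo-randomized" trial order is a seeded shuffle with a maximum run
of 3 identical trial types.

Where the design states no value, one realistic choice was made and
frozen:

* **ssVEP topography**: amplitude 2 µV at Oz, Gaussian bump of width
  35°, on a scalp-wide floor of 0.4× the peak. The floor is structural,
  not cosmetic: anterior conditioning effects (part of the default
  ground truth) are only possible if anterior sensors carry driven
  signal at all.
* **Background noise**: 1/f (slope 1) with 10 µV RMS per channel, a
  band-limited scale typical of dense-array recordings. This is the
  calibration implied by the parameter-recovery requirement the package
  tests itself against — a gain of 1.3 at five occipital sensors with
  n = 50 subjects and 30 trials per cell must, as in comparable real
  data, produce window-averaged log10BF > 2 — and it does, with margin.
* **Channel heterogeneity**: per-channel noise RMS uniform in ±30%.
  Bounded heterogeneity matters for the artifact statistics: a bounded
  across-channel index distribution keeps the maximum of clean channels
  below median + 2.5 SD deterministically, so clean data yields zero
  false flags. With perfectly homogeneous noise the index spread would
  collapse to the (tiny) signal topography and the rule would flag the
  occipital signal channels.
* **Blinks**: Poisson at 0.2 Hz, 300 ms raised-cosine, 250 µV at the
  ocular channels, propagated to scalp channels by a fixed front-to-back
  exponential weight vector (τ = 0.5 rad). The fixed vector makes the
  regression-based correction exactly identifiable.
* **Pupil**: constriction transient (γ-like, τ = 500 ms; deeper in the
  bright luminance condition) followed by re-dilation to a
  condition-specific plateau (tritan +0.24 mm, luminance −0.52 mm
  relative to baseline), a +0.06 mm CS+ increment riding on the
  plateau, 1/f² drift of 0.02 mm RMS, and Poisson blink gaps
  (0.1 Hz, 100–400 ms).
* **Expectancy ratings**: CS+ − CS− shifts of 0/3.0/4.7/3.3 points at
  the H/A1/A2/E occasions with per-cell noise SD 2.1, chosen so paired
  t-statistics land at the magnitudes a successful 50-subject
  conditioning study reports (t ≈ 7 at A1, d ≈ 1).

Two generator paths exist. The *continuous* path renders a full
recording (inter-trial intervals, blinks, bad channels, transients) and
is what the preprocessing chain is validated on. The *epoch* path emits
already-epoched signal + 1/f noise without artifact processes; it is
statistically equivalent to the continuous path after perfect artifact
control and is used for cohort-scale simulations where the statistics,
not the preprocessing, are under test. A green cohort-level test
therefore certifies the statistics pipeline given clean epochs; it does
not re-certify blink correction or SCADS, which have their own
injection-recovery tests on the continuous/artifact fixtures.

What the generator does **not** emulate: volume-conduction-correlated
noise across channels (noise is channel-independent), non-stationary
alpha bursts, eye movements other than blinks, phase drift of the driven
oscillation, or habituation of the ssVEP across trials.

## Preprocessing and artifact control

Filters are Butterworth designs applied forward-backward
(`sosfiltfilt`), so effective magnitude responses are squared and phase
is preserved. The EEG bandpass is 3–25 Hz order 4; the pupil low-pass is
order 6 with the printed cutoff of 0.03 interpreted as a *normalised*
frequency (0.03 × Nyquist = 7.5 Hz at 500 Hz) — taken literally, 0.03 Hz
would flatten a 4.4 s epoch; the literal reading stays available via
`cutoff_mode="hz"`. Pupil gaps are linearly pre-filled for the IIR pass
only (NaN would otherwise smear across the trace) and restored, so cubic
interpolation remains the documented gap-filling step.

Blink correction regresses the designated ocular channels out of every
EEG channel, with weights estimated only on segments where the ocular
envelope exceeds 4 robust SDs — i.e., on blinks, where the regressors
dominate. Ocular channels themselves are kept unmodified for audit. The
residual blink energy on synthetic forward-model data is < 5%; the
correction necessarily injects a small amount of scaled ocular noise
into scalp channels (inherent to EOG regression).

SCADS: the compound index is the mean of three median-normalised
statistics (rectified mean, SD, maximum transient change) per (trial,
channel). Global channel flags use the across-channel distribution of
the per-channel index (the *median over trials* of the per-trial
statistics — a median, so that single-trial transients remain the
trial-level rule's business); threshold median + 2.5 SD (MAD option in
config, useful when many channels fail at once and mask each other).
Trial-level channel flags share one threshold computed from the pooled
(trial, channel) index distribution; a per-trial re-estimated threshold
(config option `within_trial`) is statistically aggressive — the max of
~30 clean channels exceeds its own trial's median + 2.5 SD about a fifth
of the time. Flagged channels are rebuilt by spherical-spline
interpolation (order m = 4, 7 Legendre terms, ridge 1e-5): < 10%
relative error on smooth spatial fields at 129-sensor density. Trials
are rejected when the maximum over channels of the compound index
exceeds 1.25× the median across trials; quality is recomputed after
interpolation and before rejection. A safety rail aborts when > 20% of
channels would be globally interpolated. On defaults, the continuous
profile retains ~89% of acquisition trials per subject — the intended
regime for this kind of recording.

## Envelope extraction

The narrowband cascade is a 9th-order low-pass at 8 Hz plus a 9th-order
high-pass at 7 Hz (order of application immaterial for zero-phase LTI
filters; asserted in tests). Its zero-phase gain at 7.5 Hz is only
≈ 0.59, so by default the output is rescaled by the analytically
computed cascade gain at the driving frequency; the rescale is a single
dataset-wide constant, cancels in every CS+/CS− contrast and Bayes
factor, and can be disabled (`compensate_gain=False`) to reproduce the
uncompensated convention. The analytic signal follows the explicit
Fourier construction (double positive frequencies, zero negatives, DC
and Nyquist at unit weight) and matches `scipy.signal.hilbert` to
rounding error, which the suite uses as an independent cross-check. The
first and last 250 ms of each epoch are masked as filter warm-up; the
0–1000 and 1500–2500 ms analysis windows are unaffected, though the
cascade's ≈ ±300 ms smearing of any sharp amplitude step *is* visible at
window edges (programmed-gain recovery is exact only in window
interiors).

The amplitude spectrum is the one-sided DFT of the windowed
(default 0–3800 ms) trial average with 2/N scaling (1/N at DC/Nyquist);
frequency resolution is fixed at the reciprocal window length
(no zero-padding), so the 7.5 Hz line falls between the 7.36 and
7.63 Hz bins of the default window — the argmax lands on the nearest
bin.

## Degenerate inputs and tie-breaks

Zero-median quality parameters, all-NaN ocular channels, empty condition
cells, fully missing pupil trials, zero pooled SD in the z-transform,
and < 2 subjects all raise typed errors (`ConfigurationError`,
`DataQualityError`, `DegenerateDataError`; the CLI maps them to exit
codes 2/3). Exceedance ties count as non-exceedance (strictly greater),
matching the brute-force oracle exactly. Cluster thresholds are strict
(a sensor at exactly 2.0 is excluded).

## Known limitations

* The montage is synthetic: positions are geometrically plausible and
  the reported sensor groups are adjacent by construction, but no claim
  is made about the true net geometry.
* The average reference mixes a focal effect into all channels
  (≈ 1/n_channels leakage); on the reduced 32-sensor layout this is four
  times stronger than at 129 sensors, which is why cohort-scale
  inference tests run on the full layout.
* The envelope of signal-plus-noise is Rician-biased; small-amplitude
  sensors lose a little contrast, so recovered gains near the noise
  floor are conservative.
* The Bayesian repeated-measures ANOVA on pupil means is intentionally
  out of scope; the pupil module's deliverable is the windowed-mean
  table it would consume.
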