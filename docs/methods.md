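# Methods

`neurogut` analyses stimulus-locked responses in three recording modalities —
cortical local field potentials (LFP), scalp/epidural EEG, and duodenal
myoelectric signals — across natural sleep (slow-wave sleep, SWS) and
wakefulness, together with sorted unit spike trains.  This note documents the
models, the parameters that matter, the numerical choices, what the
synthetic-data generator does and does not emulate, and known limitations.
All empirical figures quoted below (calibration rates, operating
characteristics) are the quantities the test suite and
`scripts/acceptance.py` compute; none are asserted beyond what those runs
measure.

## Shared preprocessing (`core_signals`)

Recordings are uniformly sampled; sample `k` occurs at `start_time + k/rate`.
All windows are half-open `[start, end)` on the sample grid, with stimulus
onset at relative time 0 belonging to the post-stimulus side.

* **Filtering** — 4th-order Butterworth applied forward and backward
  (`sosfiltfilt`), so the zero-phase contract holds: no group delay, output
  length and rate unchanged.  A low band edge of 0 selects a low-pass.
* **Epoching** — rows of the trial matrix are verbatim slices of the
  recording (no resampling), so epoching is exactly invertible on retained
  spans.  Events whose window leaves the recording are dropped and reported.
* **Trial exclusion** — a trial is retained only if its full span lies inside
  a single hypnogram interval (otherwise `state_change` or `unstaged`) and
  its event carries no artifact flag.  Exclusion is idempotent and
  partitions the input exactly.
* **Baseline z-scoring** — each trial is standardised by the mean and SD of
  its own 500 ms pre-stimulus baseline.  A numerically constant baseline
  (SD ≤ 1e-12 relative) is an error naming the offending trial, never a
  silent NaN.
* **Artifact blanking** — electrical stimulation obliterates the first tens
  of milliseconds after onset.  Rather than model artifact subtraction, all
  response analyses start at +40 ms.

## Evoked LFP detection: the residual orthogonality test (`lfp_response`)

For trials `x_i(t)`, linearly detrended per trial within the analysis window
(40–540 ms after onset), every unordered pair contributes

    s_ij = Σ_t x_i(t) · x_j(t),   i < j.

If a stereotyped evoked component `a(t)` is present in every trial,
`E[s_ij] = ‖a‖²` > 0 regardless of the component's polarity; for independent
noise the pair sums scatter around zero.  The mean of the `n(n−1)/2` pair
sums is compared to zero with a one-sample t-test.  Numerically the pair
sums are read off the upper triangle of the Gram matrix `X Xᵀ`, and the
implementation is checked against both an explicit double loop and the
algebraic identity `Σ_{i<j} s_ij = (‖Σ_i x_i‖² − Σ_i ‖x_i‖²)/2`.

Choices:

* The detection verdict is **one-sided** (mean must be positive), since only
  a positive mean indicates trial-consistent structure; the two-sided p is
  reported alongside.  α = 0.05.
* Pair sums are left unnormalised (scale cancels in the t statistic); a
  per-sample mean is reported for interpretability.
* The pair sums are treated as exchangeable observations.  They are
  uncorrelated under the noise null (which is why the measured null
  rejection rate is nominal — 5.0% at 30 trials over 1000 simulations), but
  they are not independent; this is inherited from the cited procedure and
  noted rather than corrected.
* Detrending is linear per trial within the test window.

Amplitude comparison between states (run only where both states show a
significant detection): the absolute extremum of the trial-averaged z-scored
signal within the analysis window defines the peak time per state; each
trial is averaged over the 40 ms window centred there (clipped and flagged
if it would leave the analysis window); the absolute values of these
per-trial means are compared across states with the Wilcoxon rank-sum test.
Absolute values are used because evoked deflections may be negative-going;
comparing magnitudes keeps polarity out of the size question.

## Spike responses (`spike_response`)

**Density estimation.** Spike times are convolved with a unit-area Gaussian
kernel, SD υ = 20 ms (read as the SD, the convention for spike-density
kernels, not FWHM), truncated at ±4σ and renormalised, sampled on a 1 ms
grid.  Truncation renormalisation keeps the kernel exactly unit-area, so
integrating a trial's curve recovers its spike count.

**Detection criterion.** On the trial-averaged curve, a unit is responsive
in a state when some point within 40–500 ms post-stimulus deviates from the
baseline mean by more than 3 SD *and* lies inside a contiguous run of at
least 30 ms during which the deviation stays ≥ 2 SD, the run falling wholly
inside the window (runs are evaluated on the 1 ms grid with no gap
tolerance).  Onset latency is the first 3 SD crossing of the earliest
qualifying run.  Sign is excitatory/inhibitory by the run direction, dual
when both directions produce qualifying runs.

**The baseline SD unit.** The criterion needs the standard deviation of the
*averaged* baseline curve.  Estimating it as the time-wise SD of the 500 ms
averaged baseline segment is badly biased low: the kernel-smoothed curve is
autocorrelated over ~2υ = 40 ms, so a 500 ms window holds only ~16
effectively independent values and the window SD under-measures the marginal
SD.  Measured consequence: the detector false-alarms on ~24% of homogeneous
Poisson sessions.  The package therefore estimates the same quantity from
the across-trial variance of the single-trial curves (`SE = √(mean_t
var_trials / n)`), which is unbiased with ~n·500 degrees of freedom, falling
back to the window SD for single-trial curves.  Additionally, because
deviations are measured against an *estimated* baseline mean, the SD unit is
inflated by `√(1 + 2υ√π/T_b)` (≈ 1.07 at the defaults) to propagate that
estimate's variance.  A floor of 0.1 spikes/s guards silent baselines, and a
zero baseline SD yields a flagged non-significant call.

Measured operating characteristics (homogeneous Poisson trains, baseline
rates uniform on 2–50 Hz): false-positive rate ≈ 10% at 5 trials, 8% at 10,
6% at 30 — below 10% and decreasing with trial count.  The residual ~5%
floor at large n is intrinsic to the criterion: it is the probability that a
smooth Gaussian field with ~28 ms correlation length crosses 3.2 effective
SDs with 30 ms persistence somewhere in a 460 ms window, and no amount of
averaging removes it.  Consequences for population inference are discussed
under Limitations.

**Classification.** Per unit, the sleep and wake calls combine into
`sleep_only`, `wake_only`, `both_opposite` (signs differ; dual counts as
different from a pure sign), `both_same`, or `none`; `latency_differs` is
flagged when both states respond with onsets more than 50 ms apart.

## Vigilance staging and sleep disturbance (`vigilance`)

PSDs are multitaper estimates: K = 5 Slepian tapers at time-bandwidth
NW = 3 (K ≤ 2NW−1 enforced), eigenvalue-weighted average of tapered
periodograms, one-sided density normalised so its integral approximates the
signal variance (verified against Parseval and cross-checked against an
independent multitaper implementation).  Band power is the trapezoidal
integral of the density with interpolated band endpoints.  Bands: delta
1–4 Hz, spindles 7–14 Hz, gamma 30–75 Hz.

* **Staging validation** tiles each hypnogram interval with non-overlapping
  10 s windows (the same length as the disturbance windows; the staging
  window length was an open choice) and rank-sum-tests SWS vs WAKE per band.
* **Disturbance test** compares band power in `[onset−10 s, onset)` vs
  `(onset, onset+10 s]` — windows abut the stimulus with the stimulus sample
  itself excluded — paired signed-rank across events, at least 6 usable
  events, events whose windows cross a state boundary dropped and counted.
  An *awakening* verdict is any significant delta or spindle decrease or
  gamma increase; the opposite pattern raises a *somnogenic hint*.  Per-band
  α = 0.05 with no multiplicity correction, mirroring per-band reporting; a
  Bonferroni-corrected verdict is also emitted.  Note the uncorrected
  awakening verdict is an OR over three directional events of probability
  ≈ α/2 each, so its null alarm rate is ≈ 1−(1−α/2)³ ≈ 7%, not α; the
  measured rate on stationary synthetic EEG is 6–7%.  Users wanting a 5%
  verdict should use the Bonferroni flag.
* A 50 Hz notch is available as an option, default off (synthetic data has
  no mains interference).

## Gut myoelectric analysis (`myoelectric`)

Duodenal signals are modelled as sub-2 Hz pacemaker *simple waves*
(electrical control activity) with irregular 3–10 Hz *spike-potential*
bursts riding on some slow-wave crests; bursts mark actual contractions,
which occur at roughly 4–5 per minute postprandially.

* **Simple waves** — multitaper 0–2 Hz band power in the 40 s before each
  stimulus vs the 40 s starting 0.5 s after it; paired signed-rank across
  events (≥ 6), direction from the median paired difference.
* **Modulation extremum** — the post-stimulus window is band-limited to
  0–2 Hz, its analytic-signal magnitude smoothed with a 5 s moving average
  (the envelope estimator was an open choice); the envelope maximum (minimum
  for sessions whose simple-wave power decreases) defines the centre of the
  spike-potential window.  A flat envelope is flagged degenerate.
* **Spike potentials** — 3–10 Hz power in the 20 s window centred at the
  extremum (+T) vs the time-mirrored window at −T; T is clamped to ≥ 10.5 s
  so neither window touches the stimulus; events whose mirrored window
  leaves the recording are dropped and counted.
* Multitaper parameters NW = 3, K = 5 are reused from the EEG analysis.
  Visual artifact screening is replaced by the per-event artifact flag.
  The spike-potential analysis is computed for every session; gating it on
  a significant simple-wave change is left to the report consumer, and both
  are emitted.

## Synthetic data (`synthetic_data`)

All generators are pure functions of (parameters, seed): bit-identical
outputs for identical inputs.  Defaults are the study conditions the
analyses assume:

* **Stimulus trains** — i.i.d. uniform interstimulus intervals, 45–60 s for
  intestinal stimulation.  Gut sessions are simulated at ~120 s ISIs (the
  cortical-microstimulation interval of the recorded gut sessions): at
  45–60 s the previous event's 40 s effect window would overlap the next
  event's 40 s pre window by ~28 s and erase the paired contrast.
* **EEG** — per-band unit-variance band-limited Gaussian noise scaled by
  state-dependent amplitude gains switching at hypnogram boundaries;
  defaults double delta and spindle amplitude and halve gamma in SWS (power
  scales as gain²).  Default rate 200 Hz (the minimum accommodating the
  75 Hz gamma edge; real-data ingestion accepts any rate ≥ 200 Hz).
* **LFP** — 1/f^β Gaussian background (β = 1; coloured rather than white so
  the detrending step is exercised by realistic spectra) plus, for events in
  the expressing state, a causal alpha-function kernel
  `(t/τ)·exp(1−t/τ)`, τ = duration/5, scaled to the requested peak in
  noise-SD units; biphasic (alpha minus delayed alpha) for dual responses.
  The alpha kernel is a standard single-peak parameterisation; the true
  evoked waveshape (and SNR) of real recordings is unknown, so simulation
  amplitudes are calibration choices, not facts about the animal data.
* **Spikes** — inhomogeneous Poisson by thinning on a 1 ms rate grid.
  Excitatory specs add an alpha-kernel bump with peak amplitude in Hz;
  inhibitory specs multiply the rate by `1 − depth·kernel` (depth clipped to
  [0, 1], so the rate approaches zero without going negative); dual specs
  apply an excitatory lobe followed by an inhibitory one.
* **Gut** — slow-wave carrier (0.3 Hz; packets at 4–5/min match the stated
  contraction rate, the precise feline duodenal pacemaker frequency being
  unstated) with a slowly varying random amplitude (random knots every 15 s,
  linearly interpolated, clipped positive), Hann-windowed 3–10 Hz burst
  packets placed on randomly selected slow-wave crests, white measurement
  noise, and optional stimulus-locked multiplication of the slow-wave
  amplitude (and burst probability) for a configurable time after events in
  a configurable state.

What the generator does **not** emulate: REM sleep, movement and electrode
artifacts with realistic morphology, mains interference, non-Poisson spike
statistics (bursting, refractoriness), volume-conducted correlations between
channels, drifts in electrode impedance, or the true spectra/SNR of the
undeposited animal recordings.  Passing tests therefore demonstrate that the
pipeline recovers what it is designed to recover under its stated model, not
that it would reproduce the animal dataset.

## Population statistics (`report_stats`)

Fisher's exact test on 2×2 tables uses the probability-mass two-sided
convention (sum of hypergeometric probabilities of tables at most as likely
as observed) and exposes one-sided tails; it is verified against full
hypergeometric enumeration.  The site report builds the state ×
responsive/non-responsive table from the per-site detection verdicts; the
headline p for the sleep-vs-wake proportion contrast is the directional
one-sided p (which reproduces the printed population value, 0.015 on the
15/30 vs 6/30 table), with the two-sided value reported alongside.  The
per-group excess of exclusively-sleep-responsive cells is tested under two
labelled constructions — an unpaired Fisher 2×2 of exclusive counts against
totals, and an exact binomial on the discordant pair — because the original
construction is ambiguous; neither is asserted as canonical.  The responder
partition (the four responsive categories summing to the responder total) is
enforced, never assumed.

## Calibration experiments (`experiments`)

Seeded, self-contained experiments back the package's operating
characteristics: ROT null calibration (1000 noise sessions) and power (200
sessions with a 5-SD common waveform — measured power 1.0), the pairwise-sum
algebraic identity (≤ 1e-12 over 100 random instances), spike-criterion
false-positive rates, a 147-unit two-group population classification
experiment against ground truth, staging and disturbance nulls, and gut
injected-effect and null-type-I runs (simple-wave type-I measured at 4–5%
over 200 null sessions).  Problem sizes (e.g. ~27 usable trials per state in
the population experiment, 12–25 events per gut session) sit inside the
per-session trial ranges the recordings provide.

## Known limitations

* **Detector false positives propagate to population tables.**  With ~5%
  per-state false-positive probability, a 147-unit population with 86
  unresponsive units yields on the order of 10 spurious category assignments
  per run; *exact* recovery of a ground-truth category table is therefore
  not an achievable guarantee of this criterion family, and the population
  experiment reports the mismatch count instead of presuming zero.  The same
  applies to site tables under the ROT at α = 0.05.
* **Uncorrected awakening verdict exceeds α** (≈ 7% null alarm rate; see
  above).  The Bonferroni verdict is the calibrated alternative.
* **Spike-potential window placement is selection-biased.**  Centring the
  post window at the post-stimulus slow-wave envelope maximum preferentially
  samples large bursts whenever burst amplitude couples to slow-wave
  amplitude (as it does physiologically and in the generator), while the
  mirrored pre window samples an arbitrary phase.  Measured null type-I of
  the burst test is ~8–11% at α = 0.05.  This is a property of the
  specified window-placement procedure itself; results from it should be
  read accordingly.
* The t-test on ROT pair sums ignores pairwise dependence (benign under the
  null, anticonservative in edge cases with heavy-tailed noise).
* EDF files are read (via `mne`) but not written; the native interchange
  format is delimited text.
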