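# Methods note

This note records the models implemented in `humscan`, the parameter
defaults with their units and rationale, the numerical choices, and the
limitations of the synthetic generators. Everything stated as a measured
number here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from elsewhere.

## 1. Adaptive threshold estimation (`humscan.staircase`)

**Procedure.** One-up/one-down transformed staircase driving a 2AFC
detection task. Each trial presents the tone in one of two intervals; the
listener reports the interval. A correct response lowers the level by the
current down-step, an incorrect response raises it by the current up-step. A
*reversal* is a change in response correctness between consecutive trials;
the level at the flip trial is recorded.

**Step schedule** (`step_schedule_default`): the run starts at 12 dB up /
4 dB down; both steps halve at each recorded reversal until reversal 4,
after which they stay at the floor of 3 dB up / 1 dB down. All steps are in
dB, applied to the level in dB SPL.

**Stopping and estimate.** The run ends after `n_reversals = 12` reversals
(default) or `max_trials = 200` trials, whichever comes first (the latter
marks the result `incomplete`). The threshold estimate is the arithmetic
mean of the last `n_estimate = 8` reversal levels. If those 8 levels span
more than `rejection_span = 15` dB (strictly greater), the run is `rejected`
and no estimate is returned.

**Why this converges at threshold.** In equilibrium the expected level
change per trial is zero: `p·down = (1−p)·up`. With up = 3 and down = 1 this
gives p(correct) = 0.75. For an unbiased 2AFC listener,
p(correct) = (1 + p(detect))/2, so equilibrium sits at p(detect) = 0.5 — the
50%-detection level. The test suite verifies this empirically: over 1000
simulated runs against a logistic listener with threshold 45 dB SPL, the
mean estimate is within 3 dB of 45, and every run replays exactly through an
independent re-simulation of the update rules.

**Pre-reversal bump.** `apply_pre_reversal_bump` raises the level by 4 dB;
it is only legal before the first reversal (a `RuntimeError` afterwards) and
is counted in `bump_count`. It models the experimenter's option to lift the
starting region if the subject begins inaudibly low.

## 2. Test stimuli (`humscan.stimulus`)

Tones consist of a raised-cosine (cos², i.e. sin²(πt/2T)) onset ramp, a
constant plateau, and a mirrored offset ramp. Ramp and plateau durations are
whole numbers of periods, so the waveform starts and ends at zero phase.
Tabulated values (in `data/stimulus_params.csv`) cover 16, 20, 40, 63, 80
and 125 Hz. For other frequencies in the 10–200 Hz band,
`lookup_or_interpolate_params` interpolates the ramp and plateau *period
counts* linearly in log₁₀(frequency), rounds half-up to whole periods, and
derives total = 2·ramp + plateau; outside the band it raises. Rounding on
the counts rather than the durations keeps the whole-period invariant.

Plateau amplitude for a level L dB SPL is √2 · p_ref · 10^(L/20) with
p_ref = 20 µPa (`P_REF`), i.e. the level describes the plateau RMS.
`synthesize_tone` validates fs against Nyquist and clips trailing roundoff
zeros; sample count is round(total_duration · fs / 1000).

## 3. Normal hearing threshold and reference range (`humscan.thresholds`)

**NHT fit.** All control thresholds (participant × frequency points,
typically 31 participants × 6 frequencies) are pooled and fitted with a
degree-3 polynomial via `numpy.polyfit`. The default abscissa is
log₁₀(frequency), matching the roughly log-linear shape of low-frequency
thresholds; `axis="linear"` is available since the handful of distinct
frequencies does not by itself decide the question. The acceptance test
checks that both axes reproduce the generator's residual distribution, so
the choice is not load-bearing for the statistics.

**Reference range.** Residuals (threshold − fitted NHT at that frequency)
are pooled across all control points; the RR is the interval from their
2.5th to their 97.5th percentile, computed with `numpy.percentile`
(`method="linear"`). Width = upper − lower.

**Classification.** A threshold is *below the NHT* iff it is strictly less
than the fitted curve value; *within the RR* iff it is neither strictly
below NHT + lower offset nor strictly above NHT + upper offset — i.e. the
range boundaries are inclusive. The three RR categories partition the
points exactly.

**Microstructure.** For a 9-point high-resolution profile, depth is
max − min threshold; the reported extremum positions are frequency offsets
from the SPF, taking the lowest frequency on ties (first occurrence in
ascending frequency order).

**Rank-sum test.** Implemented directly: mid-ranks for ties, two-sided
normal approximation with tie-corrected variance and a 0.5 continuity
correction. `method="auto"` (the default) switches to exact enumeration of
all label assignments when n₁ + n₂ ≤ 10, where the normal approximation is
poor; `method="normal"` and `method="exact"` force either branch. The
reported z-value always comes from the normal approximation. The normal
branch agrees with `scipy.stats.mannwhitneyu(method="asymptotic")` to 1e-9
relative on 200 random instances; the exact branch is verified against
brute-force enumeration for every size pair with n₁ + n₂ ≤ 10.

**KS test.** Two-sample Kolmogorov–Smirnov via
`scipy.stats.ks_2samp(method="asymp")`; D is cross-checked against an
independent ECDF scan.

**SPF summary.** Percept-frequency matches below `MIN_VALID_SPF_HZ = 15` Hz
are treated as unreliable, excluded, and reported; the summary is the median
of the remainder.

## 4. Spectra and SOAE detection (`humscan.soae`)

**Welch estimate.** Segments of 0.5 s (Hann window), 12.5% overlap, each
zero-padded to 1 s before the FFT, so bins land on an exact 1-Hz grid.
`scipy.signal.welch` / `csd` with `scaling="spectrum"` and `detrend=False`
are used so a pure tone at an integer frequency recovers its RMS power in
its own bin exactly (zero-padding evaluates the DTFT at the tone frequency).
Levels are 10·log₁₀(power / p_ref²) dB SPL; zero-power bins get a −400 dB
sentinel (`FLOOR_LEVEL_DB`) instead of −inf. Recordings shorter than one
segment are rejected. The calibration acceptance test requires a 10 dB SPL,
1 kHz tone to read within 0.5 dB in the 1000-Hz bin; it lands within
numerical precision.

**Cross-spectrum.** For dual-microphone recordings, the magnitude of the
cross-power spectral density under the same segmentation. Noise that is
incoherent between microphones averages down by roughly √(π/4 / n_segments)
relative to the single-channel floor, while a common acoustic signal is
preserved; the tests bound both effects.

**Candidate search.** Local maxima of the (cross- or auto-) spectrum with
level ≥ −15 dB SPL inside 30–5000 Hz; peaks closer than 10 Hz are thinned
greedily by descending level.

**F-test validation.** F = peak-bin power / mean power over two 8-Hz noise
bands whose inner edges sit 20 Hz below and above the peak (bins in
[f−28, f−20) and (f+20, f+28]). A candidate is valid iff F > 5.39 strictly;
F exactly at the critical value fails. If either noise band falls outside
the spectrum the candidate is unvalidatable (F = NaN, invalid).

**Session logic.** Per ear, candidates from repeated recordings are merged
when within 10 Hz (the first-seen frequency is kept). When both ears were
recorded, lines within 10 Hz of each other across ears are removed from
*both* — they are assumed to be a common artifact (equipment line,
environmental tone), since genuine emissions of the two cochleae are not
frequency-locked.

**Interpretation of F > 5.39.** The threshold is treated as a fixed
detector operating point, not as an exact distributional quantile: the
averaged Welch bins are not independent χ² variates under overlap and
windowing, so the nominal false-alarm rate is approximate. The measured
behaviour is what the acceptance tests pin down: ≥ 95/100 detections for a
tone 15 dB above the local per-bin floor in 30-s sessions, and ≤ 0.2 false
positives per silent 30-s session.

## 5. Synthetic generators (`humscan.synth`)

**Virtual listener.** p(detect | level L, frequency f) =
(1 − lapse) · logistic((L − θ(f)) / slope), with θ(f) log-interpolated from
the listener's threshold curve. In the 2AFC task the listener answers
correctly when it detects, and guesses uniformly otherwise. Defaults:
slope 2 dB, lapse 0 (capped at 0.1). The Monte-Carlo proportion correct
matches the closed form within 3 binomial SEs at n = 10⁴.

**Cohorts.** Each participant's thresholds are
base(f) + subject offset + ripple + noise, where base(f) is a cubic in
log₁₀(f) through (16 Hz, 88 dB), (40, 62), (80, 40), (125, 30) — a plausible
low-frequency audibility curve; subject offset ~ N(0, 5 dB); ripple is a
6-dB-amplitude sinusoid in frequency with 16-Hz period and random phase
(a stand-in for threshold microstructure); measurement noise ~ N(0, 3 dB).
The `spf_offsets` design measures at SPF + {0, ±1, ±2, ±4, ±8} Hz, with SPF
drawn log-normally (median 50 Hz, spread 0.2 log₁₀ units, clipped at 15 Hz,
rounded to integers); the standard design uses the 16–125 Hz grid. These
defaults are chosen for realism of magnitudes, not fitted to any dataset;
the acceptance tests assert only generator-truth relations and
Monte-Carlo-oracle quantities about them.

**Recordings.** Noise is synthesised in the frequency domain with a
−10 dB/decade spectral slope and a floor of −20 dB SPL per 1-Hz analysis
bin at 1 kHz; the per-bin target is converted to a PSD via the analysis
ENBW of 3 Hz (Hann, 0.5-s segments: 1.5 · fs / nperseg). A
`coherent_fraction` of the noise power is shared between the two simulated
microphones; the rest is independent per channel. Emissions are tones with
optional sinusoidal frequency undulation (depth capped at 10 Hz so a real
emission never trips the 10-Hz merge/artifact logic). Sampling rate must be
≥ 2.5× the highest tone frequency.

**Problem sizes.** The detector tests and the acceptance script use 30-s,
10-kHz (or 12-kHz where tones approach 4 kHz) sessions: ~68 Welch segments,
enough averaging for the F-test to be stable while keeping the whole suite
fast. These sizes are this package's choice for validation economy; the
detector itself accepts any duration ≥ 0.5 s.

## 6. Numerical and I/O choices

- Percentiles: `numpy.percentile(method="linear")` throughout.
- Polynomial fits: `numpy.polyfit` / `numpy.polyval` (degree 3; ≥ 4 distinct
  frequencies required).
- Audio I/O: WAV via `scipy.io.wavfile` (float32 on write; integer formats
  normalised to full scale on read) plus a JSON sidecar that must provide
  `calibration_pa_per_unit` and `ear` — samples are always pascals
  internally.
- Threshold tables: long-format CSV with row-addressed validation errors.
- Spreadsheet import: `pandas.read_excel` (openpyxl) with a user-supplied
  column map and decimal-comma normalisation.
- Every CLI output gets a `*.provenance.json` sidecar (command, parameters,
  package version) for reproducibility.
- All randomness flows through `numpy.random.default_rng` seeds; no global
  seeding.

## 7. Limitations

- The cohort and recording generators emulate the *structure* of the study
  inputs (group sizes, designs, measurement grids, dual-microphone
  recordings), not any particular dataset; quantities computed on them
  (reference-range width, classification percentages, depth medians) are
  properties of the generator defaults, not empirical findings.
- The ripple model is a fixed-period sinusoid; real threshold
  microstructure is irregular and frequency-dependent.
- The F-test critical value is used as an operating point; no claim is made
  about its exact distribution under Welch averaging with overlap.
- Staircase rejection (15-dB span) and the RR percentile method involve
  conventions (strict vs. inclusive comparisons) that are documented above
  and pinned by tests, but other conventions exist.
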