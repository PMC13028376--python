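# humscan

Tools for investigating low-frequency sound percepts ("the hum"): adaptive
low-frequency hearing-threshold estimation, normal-threshold reference
ranges, threshold-microstructure statistics, and spontaneous otoacoustic
emission (SOAE) detection in calibrated ear-canal recordings.

A small fraction of the population reports a near-constant humming or
rumbling low-frequency percept that people around them cannot hear. Two
auditory explanations are testable: unusually sensitive low-frequency
hearing (including fine-grained threshold microstructure), and audible
low-frequency SOAEs. `humscan` implements the full measurement-analysis
chain needed to test both, plus synthetic generators for every input, so the
pipeline can be exercised and validated end to end without any participant
data.

## What it computes

**Adaptive thresholds.** A one-up/one-down staircase combined with a
two-alternative forced-choice (2AFC) task: a correct interval identification
lowers the tone level, a wrong one raises it. Steps shrink from 12 dB
up / 4 dB down to 3 dB up / 1 dB down as reversal points accumulate; the run
ends after 12 reversals and the threshold estimate is the mean level over
the last 8. With final steps of 3 dB up and 1 dB down the procedure
stabilises where *p*(correct) = 3/(3+1) = 0.75, i.e. at the 50%-detection
level of the 2AFC psychometric function — the listener's threshold. Runs
whose last 8 reversal levels span more than 15 dB are rejected as
inconsistent. Test tones are cos²-ramped whole-period sinusoids with
frequency-dependent durations, interpolated on a log-frequency axis for
untabulated frequencies.

**Reference ranges.** Control-group thresholds at six standard frequencies
(16–125 Hz) are pooled and fitted with a cubic polynomial on log₁₀(f) — the
normal hearing threshold (NHT). The reference range (RR) around the NHT is
bounded by the 2.5th and 97.5th percentiles of the control residuals.
Individual thresholds are then classified as below/above the curve and
below/within/above the range.

**Microstructure.** High-resolution profiles (nine tones at 0, ±1, ±2, ±4,
±8 Hz around each participant's self-matched percept frequency, SPF) exhibit
threshold microstructure; its depth is max − min threshold. Group
comparisons use a two-sided Wilcoxon rank-sum test (mid-ranks, tie and
continuity corrections; exact enumeration for small samples) and a
two-sample Kolmogorov–Smirnov test on the extrema positions relative to the
SPF.

**SOAE detection.** Spectra are estimated with Welch averaging: 0.5-s Hann
segments, 12.5% overlap, each zero-padded to 1 s, giving 1-Hz bins
calibrated so a tone's peak bin reads its RMS power in dB SPL. Local maxima
≥ −15 dB SPL between 30 Hz and 5 kHz, at least 10 Hz apart, are candidate
emissions; each is validated by an F-test — peak-bin power over the mean
power in two 8-Hz noise bands 20 Hz above and below — against the critical
value 5.39 (strict). Dual-microphone recordings use the cross-power spectral
density, which suppresses noise that is incoherent between the two
microphones and lowers the floor. Lines appearing within 10 Hz in both ears
are removed as artifacts, and repeats drifting by ≤ 10 Hz count as one
emission.

## Worked example

```sh
humscan simulate cohort --seed 7 --n 31 --group CG1 --out cg1.csv
humscan simulate cohort --seed 8 --n 28 --design spf_offsets --group LFSH --out lfsh.csv
humscan fit-rr --controls cg1.csv --out rr.json
humscan classify --rr rr.json --profiles lfsh.csv
```

prints

```
RR: [-12.7, +10.6] dB (width 23.3)
{
  "n_total": 252,
  "frac_below_nht": 0.38095238095238093,
  "frac_above_nht": 0.6190476190476191,
  "frac_below_rr": 0.03571428571428571,
  "frac_within_rr": 0.8571428571428571,
  "frac_above_rr": 0.10714285714285714
}
```

— the simulated control cohort's reference range spans 23.3 dB around the
fitted NHT, and 86% of the 252 simulated high-resolution thresholds (28
participants × 9 frequencies) fall inside it, with no clustering below the
curve: the pattern expected when the tested group's hearing is drawn from
the same population as the controls.

SOAE detection on a synthetic dual-microphone recording with one embedded
emission:

```sh
humscan simulate recording --seed 9 --duration 30 --soae 2000:-3 --out ear.wav
humscan detect-soae --left ear.wav --calib ear.json --out soae.csv
```

finds exactly the injected emission:

```
ear,frequency_hz,level_db_spl,f_statistic,noise_floor_db_spl,source,valid
left,2000.0,-3.66,173.5,-26.05,dual_probe_cross,True
```

The same operations are available as library calls (`humscan.fit_nht`,
`humscan.run_staircase`, `humscan.detect_soaes`, ...); see `docs/methods.md`
for the model details and numerical choices.

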