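"""Synthetic study inputs: virtual listeners, cohorts, ear-canal recordings.

Everything the analysis pipeline consumes can be generated here without any
external data: logistic virtual listeners for staircase simulation, cohort
threshold tables with a smooth base audibility curve plus between-subject
offsets, sinusoidal threshold microstructure and measurement noise, and
calibrated dual-microphone recordings with a 1/f-shaped noise floor, a
configurable coherent/incoherent noise split, and embedded SOAE tones with
slow frequency undulation. Every generator is a pure function of its spec,
including the seed, and returns a truth record for assertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from humscan.soae import CalibratedRecording
from humscan.staircase import Responder
from humscan.stimulus import P_REF
from humscan.thresholds import (
    DEFAULT_FREQUENCIES,
    MIN_VALID_SPF_HZ,
    SPF_OFFSETS,
    ThresholdProfile,
)

# Plausible low-frequency audibility anchors (Hz, dB SPL) for the default
# base curve — fixture constants, not measured values.
_BASE_ANCHORS = ((16.0, 88.0), (40.0, 62.0), (80.0, 40.0), (125.0, 30.0))


def default_base_curve() -> np.ndarray:
    """Cubic coefficients (np.polyval order) on log10(f) through the anchors."""
    f, t = zip(*_BASE_ANCHORS)
    return np.polyfit(np.log10(f), t, 3)


@dataclass
class VirtualListener:
    """Logistic psychometric observer for 2AFC staircase simulation.

    Detection probability at level L is ``(1 - lapse_rate) * logistic((L -
    threshold)/slope)``; a detected tone yields the correct interval, an
    undetected one a fair-coin guess, so proportion correct is floored at
    0.5 and capped at ``1 - lapse_rate/2``. ``threshold_curve`` maps
    frequency to the 50%-detection level and is interpolated linearly in
    log10(f) between entries.
    """

    threshold_curve: dict[float, float]
    slope: float = 2.0
    lapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not self.threshold_curve:
            raise ValueError("threshold_curve must be non-empty")

    def threshold_at(self, frequency: float) -> float:
        freqs = np.array(sorted(self.threshold_curve))
        thr = np.array([self.threshold_curve[f] for f in freqs])
        return float(np.interp(math.log10(frequency), np.log10(freqs), thr))

    def detection_probability(self, level: float, frequency: float) -> float:
        x = (level - self.threshold_at(frequency)) / self.slope
        return (1.0 - self.lapse_rate) / (1.0 + math.exp(-x))


def make_listener(spec: VirtualListener, frequency: float) -> Responder:
    """Response source for :func:`humscan.staircase.run_staircase`.

    Uses the listener's own seeded generator, so the trial-by-trial
    behaviour is fully reproducible from (listener seed, staircase seed).
    """
    rng = np.random.default_rng(spec.seed)

    def respond(level: float, signal_interval: int, _staircase_rng) -> int:
        if rng.random() < spec.detection_probability(level, frequency):
            return signal_interval
        return int(rng.integers(1, 3))  # 2AFC guess

    return respond


@dataclass
class SyntheticCohortSpec:
    """Cohort of threshold profiles with controllable microstructure.

    Per participant: ``threshold(f) = base cubic(log10 f) + subject offset +
    ripple_amplitude * sin(2*pi*f/ripple_period + subject phase) + noise``.
    ``design`` selects the test-frequency layout: the six standard control
    frequencies, or nine frequencies at offsets {0, ±1, ±2, ±4, ±8} Hz
    around each participant's matched percept frequency (SPF).
    """

    n_participants: int = 31
    base_curve: np.ndarray | None = None  # cubic coeffs on log10(f)
    between_subject_sd: float = 5.0
    ripple_amplitude: float = 6.0
    ripple_period: float = 16.0
    measurement_noise_sd: float = 3.0
    spf_median: float = 50.0
    spf_log10_spread: float = 0.2
    design: Literal["default_frequencies", "spf_offsets"] = "default_frequencies"
    group: str = "CG1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_curve is None:
            self.base_curve = default_base_curve()
        self.base_curve = np.asarray(self.base_curve, dtype=float)
        for name in ("between_subject_sd", "ripple_amplitude", "measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CohortTruth:
    """Latent values behind a generated cohort."""

    base_curve: np.ndarray
    subject_offsets: np.ndarray
    ripple_phases: np.ndarray
    spfs: np.ndarray | None

    def true_threshold(self, participant: int, f: np.ndarray, spec: SyntheticCohortSpec) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return (
            np.polyval(self.base_curve, np.log10(f))
            + self.subject_offsets[participant]
            + spec.ripple_amplitude
            * np.sin(2 * np.pi * f / spec.ripple_period + self.ripple_phases[participant])
        )


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[ThresholdProfile], CohortTruth]:
    rng = np.random.default_rng(spec.seed)
    offsets = rng.normal(0.0, spec.between_subject_sd, spec.n_participants)
    phases = rng.uniform(0.0, 2 * np.pi, spec.n_participants)
    spfs = None
    if spec.design == "spf_offsets":
        raw = spec.spf_median * 10.0 ** rng.normal(0.0, spec.spf_log10_spread, spec.n_participants)
        # matched with a 1-Hz step tone generator, never below the validity floor
        spfs = np.maximum(np.round(raw), MIN_VALID_SPF_HZ)
    truth = CohortTruth(
        base_curve=spec.base_curve.copy(),
        subject_offsets=offsets,
        ripple_phases=phases,
        spfs=spfs,
    )
    profiles: list[ThresholdProfile] = []
    for i in range(spec.n_participants):
        if spec.design == "spf_offsets":
            freqs = spfs[i] + np.asarray(SPF_OFFSETS)
            spf = float(spfs[i])
        else:
            freqs = np.asarray(DEFAULT_FREQUENCIES)
            spf = None
        noise = rng.normal(0.0, spec.measurement_noise_sd, len(freqs))
        thresholds = truth.true_threshold(i, freqs, spec) + noise
        profiles.append(
            ThresholdProfile(
                participant_id=f"{spec.group}{i + 1:02d}",
                ear="left" if rng.random() < 0.5 else "right",
                frequencies=freqs,
                thresholds=thresholds,
                spf=spf,
                group=spec.group,
            )
        )
    return profiles, truth


@dataclass
class SyntheticRecordingSpec:
    """Dual-microphone ear-canal recording with embedded SOAE tones.

    ``soaes`` lists (frequency Hz, level dB SPL, undulation depth Hz,
    undulation period s) per tone. The noise floor is 1/f-shaped and split
    into a component common to both microphones (acoustic, fraction
    ``coherent_fraction`` of the noise power) and independent per-channel
    components (instrumentation noise). Levels are calibrated so a 1-Hz-bin
    Welch analysis (0.5-s Hann segments zero-padded to 1 s) recovers the
    specified per-bin floor and tone levels.
    """

    duration: float = 120.0
    sampling_rate: float = 10000.0
    soaes: Sequence[tuple[float, float, float, float]] = ()
    noise_floor_level_at_1khz: float = -20.0  # dB SPL per 1-Hz bin
    noise_slope: float = -10.0  # dB per decade, 1/f-like
    coherent_fraction: float = 0.5
    ear: Literal["left", "right"] = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coherent_fraction <= 1:
            raise ValueError("coherent_fraction must be in [0, 1]")
        for f0, _, depth, _ in self.soaes:
            if depth > 10:
                raise ValueError("undulation depth above 10 Hz would split one emission")
            if self.sampling_rate < 2.5 * f0:
                raise ValueError("sampling_rate must be at least 2.5x the highest SOAE")


#: Equivalent noise bandwidth of the analysis (0.5-s Hann segments), Hz.
_ANALYSIS_ENBW_HZ = 3.0


def _shaped_noise(
    rng: np.random.Generator, n: int, fs: float, psd: np.ndarray
) -> np.ndarray:
    """Gaussian noise of length ``n`` with one-sided PSD ``psd`` (Pa²/Hz),
    given on the rfft grid, via frequency-domain colouring."""
    n_bins = n // 2 + 1
    mag = np.sqrt(psd * fs * n / 2.0)
    x = mag * (rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)) / math.sqrt(2)
    x[0] = 0.0
    if n % 2 == 0:
        x[-1] = x[-1].real * math.sqrt(2)
    return np.fft.irfft(x, n=n)


def generate_recording(
    spec: SyntheticRecordingSpec,
) -> tuple[CalibratedRecording, dict]:
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    fs = spec.sampling_rate
    freqs = np.fft.rfftfreq(n, 1.0 / fs)

    # per-bin floor target -> PSD: the analysis bins integrate one ENBW of PSD
    f_safe = np.maximum(freqs, 1.0)
    bin_level = spec.noise_floor_level_at_1khz + spec.noise_slope * np.log10(f_safe / 1000.0)
    psd = (P_REF**2) * 10.0 ** (bin_level / 10.0) / _ANALYSIS_ENBW_HZ

    shared = _shaped_noise(rng, n, fs, psd * spec.coherent_fraction)
    indep1 = _shaped_noise(rng, n, fs, psd * (1.0 - spec.coherent_fraction))
    indep2 = _shaped_noise(rng, n, fs, psd * (1.0 - spec.coherent_fraction))

    t = np.arange(n) / fs
    tones = np.zeros(n)
    for f0, level, depth, period in spec.soaes:
        amplitude = math.sqrt(2.0) * P_REF * 10.0 ** (level / 20.0)
        if depth > 0 and period > 0:
            # sinusoidal FM: instantaneous frequency f0 + (depth/2) sin(2πt/T)
            phase = 2 * np.pi * (
                f0 * t - (depth / 2.0) * (period / (2 * np.pi)) * (np.cos(2 * np.pi * t / period) - 1.0)
            )
        else:
            phase = 2 * np.pi * f0 * t
        tones = tones + amplitude * np.sin(phase)

    samples = np.vstack([shared + indep1 + tones, shared + indep2 + tones])
    rec = CalibratedRecording(samples=samples, sampling_rate=fs, ear=spec.ear)
    truth = {
        "soaes": [
            {"frequency_hz": f0, "level_db_spl": lv, "undulation_depth_hz": d, "undulation_period_s": p}
            for f0, lv, d, p in spec.soaes
        ],
        "noise_floor_level_at_1khz_db": spec.noise_floor_level_at_1khz,
        "noise_slope_db_per_decade": spec.noise_slope,
        "coherent_fraction": spec.coherent_fraction,
        "seed": spec.seed,
    }
    return rec, truth
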