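"""Spontaneous otoacoustic emission (SOAE) detection in ear-canal recordings.

SOAEs are narrowband sounds emitted by the inner ear, measurable with a
sensitive microphone sealed in the ear canal. Detection runs on averaged
spectra with 1-Hz bins: 0.5-s Hann-windowed segments with 12.5% overlap,
each zero-padded to 1 s before the FFT. Candidate peaks (local maxima at or
above −15 dB SPL, at least 10 Hz apart, between 30 Hz and 5 kHz) are
validated with an F-test against the averaged power in two 8-Hz-wide noise
bands flanking the peak, and spectral lines appearing at nearly the same
frequency in both ears are discarded as instrumentation artifacts.

Dual-microphone probes allow cross-power-spectral-density analysis, which
averages away noise that is incoherent between the two microphones (e.g.
electrical noise in the two recording chains) and thereby lowers the
effective noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import signal

from humscan.stimulus import P_REF

#: Level reported for empty (zero-power) bins, dB SPL.
FLOOR_LEVEL_DB = -400.0

#: Default candidate search band, Hz.
SEARCH_BAND = (30.0, 5000.0)

#: Default peak-validation F-test critical value.
F_CRITICAL = 5.39


@dataclass
class CalibratedRecording:
    """Ear-canal pressure recording, one or two microphone channels.

    ``samples`` has shape (n_channels, n_samples) and is in pascals after
    applying ``calibration`` (Pa per digital unit) upstream.
    """

    samples: np.ndarray
    sampling_rate: float
    ear: Literal["left", "right"]
    calibration: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] not in (1, 2):
            raise ValueError("recordings must have 1 or 2 channels")

    @property
    def channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class SpectrumEstimate:
    """Averaged power spectrum on a 1-Hz bin grid."""

    frequencies: np.ndarray
    power: np.ndarray  # Pa^2 per bin (mean-square of a tone in the bin)
    method: Literal["auto", "cross"]
    n_segments: int

    @property
    def level(self) -> np.ndarray:
        """dB SPL per bin (re 20 µPa), floor sentinel for empty bins."""
        with np.errstate(divide="ignore"):
            lev = 10.0 * np.log10(self.power / P_REF**2)
        return np.where(self.power > 0, lev, FLOOR_LEVEL_DB)


@dataclass
class SoaeCandidate:
    frequency: float
    level: float
    ear: Literal["left", "right"]
    source: Literal["single_probe", "dual_probe_cross"]
    f_statistic: float = float("nan")
    noise_floor_level: float = float("nan")
    valid: bool = False


def _welch_params(rec: CalibratedRecording) -> dict:
    fs = rec.sampling_rate
    if rec.duration < 1.0:
        raise ValueError("recording must be at least 1 s for spectral analysis")
    nperseg = int(round(0.5 * fs))
    return dict(
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(0.125 * nperseg)),
        nfft=int(round(fs)),  # zero-pad each 0.5-s segment to 1 s -> 1-Hz bins
        detrend=False,
        scaling="spectrum",
    )


def _n_segments(n_samples: int, nperseg: int, noverlap: int) -> int:
    return (n_samples - noverlap) // (nperseg - noverlap)


def welch_spectrum(rec: CalibratedRecording, channel: int = 0) -> SpectrumEstimate:
    """Welch autospectrum of one channel, calibrated so that a stationary
    sinusoid's peak bin reads the tone's mean-square power (RMS²)."""
    params = _welch_params(rec)
    f, p = signal.welch(rec.samples[channel], **params)
    nseg = _n_segments(rec.samples.shape[1], params["nperseg"], params["noverlap"])
    return SpectrumEstimate(frequencies=f, power=p, method="auto", n_segments=nseg)


def cross_spectrum(rec: CalibratedRecording) -> SpectrumEstimate:
    """Magnitude of the averaged cross-spectrum of a dual-microphone recording.

    Same grid and windowing as :func:`welch_spectrum`. Noise that is
    incoherent between the channels averages toward zero with the number of
    segments, lowering the floor below either autospectrum.
    """
    if rec.channels != 2:
        raise ValueError("cross spectrum requires a dual-channel recording")
    params = _welch_params(rec)
    f, pxy = signal.csd(rec.samples[0], rec.samples[1], **params)
    nseg = _n_segments(rec.samples.shape[1], params["nperseg"], params["noverlap"])
    return SpectrumEstimate(
        frequencies=f, power=np.abs(pxy), method="cross", n_segments=nseg
    )


def find_candidates(
    spec: SpectrumEstimate,
    ear: Literal["left", "right"],
    source: Literal["single_probe", "dual_probe_cross"] = "single_probe",
    min_level: float = -15.0,
    min_spacing: float = 10.0,
    band: tuple[float, float] = SEARCH_BAND,
) -> list[SoaeCandidate]:
    """Local spectral maxima at or above ``min_level`` inside ``band``.

    Among maxima closer together than ``min_spacing``, only the highest is
    retained (greedy, by descending level). Candidates are returned
    unvalidated.
    """
    df = np.diff(spec.frequencies)
    if len(df) and not np.allclose(df, 1.0):
        raise ValueError("spectrum must be on a 1-Hz bin grid")
    level = spec.level
    in_band = (spec.frequencies >= band[0]) & (spec.frequencies <= band[1])
    peaks, _ = signal.find_peaks(level, height=min_level)
    peaks = [p for p in peaks if in_band[p]]
    peaks.sort(key=lambda p: -level[p])
    kept: list[int] = []
    for p in peaks:
        if all(abs(spec.frequencies[p] - spec.frequencies[q]) >= min_spacing for q in kept):
            kept.append(p)
    kept.sort(key=lambda p: spec.frequencies[p])
    return [
        SoaeCandidate(
            frequency=float(spec.frequencies[p]),
            level=float(level[p]),
            ear=ear,
            source=source,
        )
        for p in kept
    ]


def f_test_validate(
    spec: SpectrumEstimate,
    candidate: SoaeCandidate,
    critical: float = F_CRITICAL,
    band_width: float = 8.0,
    band_offset: float = 20.0,
) -> SoaeCandidate:
    """Validate a candidate against the local noise floor.

    The F statistic is the peak-bin power divided by the mean power over two
    ``band_width``-Hz noise bands whose inner edges sit ``band_offset`` Hz
    above and below the peak. Validity requires F strictly greater than
    ``critical``. Candidates whose noise bands fall outside the spectrum are
    returned unvalidatable (``valid=False``, F = nan).
    """
    f = spec.frequencies
    idx = int(np.argmin(np.abs(f - candidate.frequency)))
    lo_band = (candidate.frequency - band_offset - band_width, candidate.frequency - band_offset)
    hi_band = (candidate.frequency + band_offset, candidate.frequency + band_offset + band_width)
    if lo_band[0] < f[0] or hi_band[1] > f[-1]:
        return replace(candidate, f_statistic=float("nan"), valid=False)
    noise_mask = ((f >= lo_band[0]) & (f < lo_band[1])) | ((f > hi_band[0]) & (f <= hi_band[1]))
    noise_mean = float(np.mean(spec.power[noise_mask]))
    peak_power = float(spec.power[idx])
    if noise_mean <= 0:
        fstat = float("inf") if peak_power > 0 else float("nan")
    else:
        fstat = peak_power / noise_mean
    with np.errstate(divide="ignore"):
        noise_level = (
            10.0 * np.log10(noise_mean / P_REF**2) if noise_mean > 0 else FLOOR_LEVEL_DB
        )
    return replace(
        candidate,
        f_statistic=fstat,
        noise_floor_level=float(noise_level),
        valid=bool(fstat > critical),
    )


def binaural_artifact_filter(
    left: Sequence[SoaeCandidate],
    right: Sequence[SoaeCandidate],
    tolerance: float = 10.0,
) -> tuple[list[SoaeCandidate], list[SoaeCandidate]]:
    """Drop spectral lines found at nearly the same frequency in both ears.

    A true emission occurring at (almost) identical frequencies in both ears
    is improbable, so every left–right pair within ``tolerance`` Hz
    (inclusive) removes both members as presumed artifacts.
    """
    drop_left = {
        i
        for i, c in enumerate(left)
        if any(abs(c.frequency - r.frequency) <= tolerance for r in right)
    }
    drop_right = {
        j
        for j, c in enumerate(right)
        if any(abs(c.frequency - l.frequency) <= tolerance for l in left)
    }
    return (
        [c for i, c in enumerate(left) if i not in drop_left],
        [c for j, c in enumerate(right) if j not in drop_right],
    )


def merge_candidates(
    existing: Sequence[SoaeCandidate],
    new: Sequence[SoaeCandidate],
    tolerance: float = 10.0,
) -> list[SoaeCandidate]:
    """Merge a new detection list into an ear's emission list.

    Emissions undulate slowly in frequency, so a new candidate within
    ``tolerance`` Hz (inclusive) of an already identified one is counted as
    the same emission (the existing entry is kept); the rest are appended.
    """
    merged = list(existing)
    for cand in new:
        if not any(abs(cand.frequency - e.frequency) <= tolerance for e in merged):
            merged.append(cand)
    return merged


def detect_soaes(
    session: Mapping[str, Sequence[CalibratedRecording]],
    critical: float = F_CRITICAL,
    min_level: float = -15.0,
    min_spacing: float = 10.0,
    band: tuple[float, float] = SEARCH_BAND,
    merge_tolerance: float = 10.0,
    binaural_tolerance: float = 10.0,
) -> dict[str, list[SoaeCandidate]]:
    """Full detection pipeline for one participant session.

    ``session`` maps ear ("left"/"right") to its recordings (repeats and/or
    probes; any settling period at the start of a measurement is assumed to
    have been trimmed upstream). Per recording: spectrum (cross-spectrum for
    dual-channel, Welch autospectrum otherwise) → candidate peaks → F-test
    validation; validated emissions are merged across recordings per ear,
    then lines shared between the ears are removed as artifacts.
    """
    if not session or all(len(v) == 0 for v in session.values()):
        raise ValueError("session has no recordings")
    per_ear: dict[str, list[SoaeCandidate]] = {}
    for ear, recs in session.items():
        merged: list[SoaeCandidate] = []
        for rec in recs:
            if rec.ear != ear:
                raise ValueError("recording ear label inconsistent with session key")
            if rec.channels == 2:
                spec = cross_spectrum(rec)
                source = "dual_probe_cross"
            else:
                spec = welch_spectrum(rec, 0)
                source = "single_probe"
            cands = find_candidates(
                spec, ear=ear, source=source, min_level=min_level,
                min_spacing=min_spacing, band=band,
            )
            valid = [
                c
                for c in (f_test_validate(spec, c, critical=critical) for c in cands)
                if c.valid
            ]
            merged = merge_candidates(merged, valid, tolerance=merge_tolerance)
        per_ear[ear] = merged
    if "left" in per_ear and "right" in per_ear:
        per_ear["left"], per_ear["right"] = binaural_artifact_filter(
            per_ear["left"], per_ear["right"], tolerance=binaural_tolerance
        )
    return per_ear
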