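"""Pure-tone test stimuli with squared-cosine onset/offset ramps.

Low-frequency test tones are specified as whole numbers of stimulus periods:
``ramp_periods`` rising periods, ``full_amplitude_periods`` at plateau, and
``ramp_periods`` falling periods. Period counts at frequencies not in the
built-in parameter table are interpolated linearly in log10(frequency) and
rounded to the nearest integer (half up), so the period bookkeeping stays
exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

#: Reference pressure for dB SPL, pascals.
P_REF = 20e-6


@dataclass(frozen=True)
class ToneStimulusSpec:
    """Frequency-dependent timing parameters and level for one test tone.

    Durations are in milliseconds; ``level`` is the plateau level in dB SPL
    (re 20 µPa RMS).
    """

    frequency: float
    total_periods: int
    ramp_periods: int
    full_amplitude_periods: int
    period_duration: float
    total_duration: float
    level: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.total_periods != 2 * self.ramp_periods + self.full_amplitude_periods:
            raise ValueError(
                "total_periods must equal 2*ramp_periods + full_amplitude_periods"
            )
        if abs(self.period_duration - 1000.0 / self.frequency) > 0.1:
            raise ValueError("period_duration inconsistent with frequency")
        if abs(self.total_duration - self.total_periods * self.period_duration) > 1.0:
            raise ValueError("total_duration inconsistent with period count")

    def with_level(self, level: float) -> "ToneStimulusSpec":
        return ToneStimulusSpec(
            self.frequency,
            self.total_periods,
            self.ramp_periods,
            self.full_amplitude_periods,
            self.period_duration,
            self.total_duration,
            level,
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def load_stimulus_table() -> list[ToneStimulusSpec]:
    """Load the packaged per-frequency stimulus parameter table.

    Rows are sorted by frequency. The tabulated total durations are kept
    verbatim (they are rounded to whole ms in the source table, e.g. 604 ms
    at 63 Hz where 38 periods of 15.873 ms give 603.2 ms).
    """
    rows: list[ToneStimulusSpec] = []
    path = resources.files("humscan.data").joinpath("stimulus_params.csv")
    with path.open() as fh:
        header = fh.readline()
        assert header.startswith("frequency_hz")
        for line in fh:
            f, tot, ramp, full, per, total_ms = line.strip().split(",")
            rows.append(
                ToneStimulusSpec(
                    frequency=float(f),
                    total_periods=int(tot),
                    ramp_periods=int(ramp),
                    full_amplitude_periods=int(full),
                    period_duration=float(per),
                    total_duration=float(total_ms),
                )
            )
    rows.sort(key=lambda r: r.frequency)
    return rows


def lookup_or_interpolate_params(
    frequency: float,
    table: list[ToneStimulusSpec] | None = None,
    *,
    band: tuple[float, float] = (10.0, 200.0),
) -> ToneStimulusSpec:
    """Return tone parameters at ``frequency``, interpolating if untabulated.

    At a tabulated frequency the table row is returned exactly. Otherwise
    ramp and full-amplitude period counts are interpolated linearly in
    log10(frequency) between the bracketing rows (or extrapolated from the
    nearest pair), rounded half up; the total count is derived from them so
    the period bookkeeping invariant holds. Frequencies outside ``band``
    raise ``ValueError``.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if not band[0] <= frequency <= band[1]:
        raise ValueError(
            f"frequency {frequency} Hz outside extrapolation band {band}"
        )
    if table is None:
        table = load_stimulus_table()
    if not table:
        raise ValueError("empty parameter table")

    for row in table:
        if row.frequency == frequency:
            return row

    freqs = [r.frequency for r in table]
    # bracketing pair, or nearest edge pair for extrapolation
    hi = next((i for i, f in enumerate(freqs) if f > frequency), None)
    if hi is None:
        lo, hi = len(table) - 2, len(table) - 1
    elif hi == 0:
        lo, hi = 0, 1
    else:
        lo = hi - 1
    a, b = table[lo], table[hi]
    t = (math.log10(frequency) - math.log10(a.frequency)) / (
        math.log10(b.frequency) - math.log10(a.frequency)
    )
    ramp = _round_half_up(a.ramp_periods + t * (b.ramp_periods - a.ramp_periods))
    full = _round_half_up(
        a.full_amplitude_periods
        + t * (b.full_amplitude_periods - a.full_amplitude_periods)
    )
    ramp = max(ramp, 1)
    full = max(full, 0)
    total = 2 * ramp + full
    period_ms = 1000.0 / frequency
    return ToneStimulusSpec(
        frequency=frequency,
        total_periods=total,
        ramp_periods=ramp,
        full_amplitude_periods=full,
        period_duration=period_ms,
        total_duration=total * period_ms,
    )


def synthesize_tone(
    spec: ToneStimulusSpec,
    sampling_rate: float,
    *,
    pascals_per_unit: float = 1.0,
) -> np.ndarray:
    """Render ``spec`` as a sampled pressure waveform.

    The sinusoid starts at phase zero; the first and last ``ramp_periods``
    periods are shaped with a squared-cosine envelope (0→1 rise, 1→0 fall).
    The plateau RMS corresponds to ``spec.level`` dB SPL re 20 µPa under the
    ``pascals_per_unit`` calibration (default: samples are physical pascals).
    """
    if sampling_rate < 10 * spec.frequency:
        raise ValueError("sampling_rate must be at least 10x the tone frequency")

    # exact period bookkeeping, not the (rounded) tabulated total_duration
    duration_s = spec.total_periods * (1000.0 / spec.frequency) / 1000.0
    n = round(spec.total_duration * sampling_rate / 1000.0)
    t = np.arange(n) / sampling_rate

    amplitude_pa = math.sqrt(2.0) * P_REF * 10.0 ** (spec.level / 20.0)
    x = (amplitude_pa / pascals_per_unit) * np.sin(2 * np.pi * spec.frequency * t)

    ramp_s = spec.ramp_periods * (1000.0 / spec.frequency) / 1000.0
    env = np.ones(n)
    rise = t < ramp_s
    env[rise] = np.sin(0.5 * np.pi * t[rise] / ramp_s) ** 2
    fall = t > duration_s - ramp_s
    env[fall] = np.sin(0.5 * np.pi * np.clip(duration_s - t[fall], 0, ramp_s) / ramp_s) ** 2
    return x * env
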