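"""Normal-threshold reference ranges and threshold-microstructure statistics.

A cubic "normal hearing threshold" (NHT) curve is fitted to pooled
control-group thresholds by ordinary least squares on the configured
frequency axis (log10 by default). The reference range (RR) around that
curve is bounded by the 2.5th and 97.5th percentiles of the control
residuals (measured − fitted), using linear interpolation between order
statistics. Individual thresholds are then classified against the NHT
(strictly below/above the curve) and the RR (inclusive boundaries).

Microstructure depth is the span between a profile's highest and lowest
threshold across its closely spaced test frequencies; group comparisons use
a two-sided Wilcoxon rank-sum test (normal approximation with mid-ranks, tie
and continuity corrections) and a two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

#: Self-matched percept frequencies below this are treated as unreliable.
MIN_VALID_SPF_HZ = 15.0

#: The six standard test-tone frequencies for control measurements, Hz.
DEFAULT_FREQUENCIES = (16.0, 20.0, 40.0, 63.0, 80.0, 125.0)

#: Test-tone offsets (Hz) around the matched percept frequency for
#: high-resolution profiles.
SPF_OFFSETS = (-8.0, -4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0, 8.0)


@dataclass
class ThresholdProfile:
    """One participant-ear's thresholds over a set of test frequencies."""

    participant_id: str
    ear: Literal["left", "right"]
    frequencies: np.ndarray
    thresholds: np.ndarray
    spf: float | None = None
    group: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.frequencies.shape != self.thresholds.shape:
            raise ValueError("frequencies and thresholds must have equal length")
        if len(self.frequencies) and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.spf is not None and self.spf < MIN_VALID_SPF_HZ:
            raise ValueError(f"spf below {MIN_VALID_SPF_HZ} Hz is not considered reliable")


@dataclass
class NhtModel:
    """Cubic normal-hearing-threshold curve on a linear or log10 axis."""

    coefficients: np.ndarray  # highest order first, np.polyval convention
    fit_domain: tuple[float, float]
    axis: Literal["linear", "log10"] = "log10"

    def predict(self, frequencies: Sequence[float] | np.ndarray) -> np.ndarray:
        f = np.asarray(frequencies, dtype=float)
        x = np.log10(f) if self.axis == "log10" else f
        return np.polyval(self.coefficients, x)


@dataclass
class ReferenceRange:
    lower_offset: float  # dB, <= 0
    upper_offset: float  # dB, >= 0
    lower_percentile: float = 2.5
    upper_percentile: float = 97.5

    @property
    def width(self) -> float:
        return self.upper_offset - self.lower_offset


@dataclass
class ClassificationSummary:
    n_total: int
    frac_below_nht: float
    frac_above_nht: float
    frac_below_rr: float
    frac_within_rr: float
    frac_above_rr: float


@dataclass
class MicrostructureSummary:
    depth: float
    max_frequency: float
    min_frequency: float
    max_offset_from_spf: float | None = None
    min_offset_from_spf: float | None = None


@dataclass
class RankSumResult:
    rank_sum: float  # sum of sample_a's mid-ranks
    rank_sum_b: float  # sum of sample_b's mid-ranks (complement)
    z_value: float
    p_value: float


@dataclass
class KsResult:
    d_statistic: float
    p_value: float


def _pooled_points(profiles: Iterable[ThresholdProfile]) -> tuple[np.ndarray, np.ndarray]:
    f = np.concatenate([p.frequencies for p in profiles])
    t = np.concatenate([p.thresholds for p in profiles])
    return f, t


def fit_nht(
    profiles: Sequence[ThresholdProfile],
    axis: Literal["linear", "log10"] = "log10",
    degree: int = 3,
) -> NhtModel:
    """Least-squares cubic fit to all (frequency, threshold) points pooled
    across ``profiles``."""
    f, t = _pooled_points(profiles)
    if len(np.unique(f)) < degree + 1:
        raise ValueError(f"need at least {degree + 1} distinct frequencies")
    x = np.log10(f) if axis == "log10" else f
    coeffs = np.polyfit(x, t, degree)
    return NhtModel(
        coefficients=coeffs,
        fit_domain=(float(f.min()), float(f.max())),
        axis=axis,
    )


def compute_reference_range(
    model: NhtModel,
    profiles: Sequence[ThresholdProfile],
    lower_percentile: float = 2.5,
    upper_percentile: float = 97.5,
) -> ReferenceRange:
    """Residual-percentile reference range around the fitted curve.

    Offsets are the requested percentiles of (measured − fitted) over all
    points, computed with linear interpolation between order statistics.
    """
    f, t = _pooled_points(profiles)
    if len(t) < 2:
        raise ValueError("need at least 2 points for a reference range")
    residuals = t - model.predict(f)
    lo, hi = np.percentile(
        residuals, [lower_percentile, upper_percentile], method="linear"
    )
    return ReferenceRange(
        lower_offset=float(lo),
        upper_offset=float(hi),
        lower_percentile=lower_percentile,
        upper_percentile=upper_percentile,
    )


def classify_thresholds(
    profiles: Sequence[ThresholdProfile],
    model: NhtModel,
    rr: ReferenceRange,
) -> ClassificationSummary:
    """Label every threshold point against the NHT curve and the RR band.

    "Below the NHT" is strict (< the fitted value; equality counts as above),
    while the RR boundaries are inclusive (a point exactly on a limit is
    within the range).
    """
    f, t = _pooled_points(profiles)
    fitted = model.predict(f)
    n = len(t)
    below_nht = np.sum(t < fitted)
    below_rr = np.sum(t < fitted + rr.lower_offset)
    above_rr = np.sum(t > fitted + rr.upper_offset)
    return ClassificationSummary(
        n_total=int(n),
        frac_below_nht=below_nht / n,
        frac_above_nht=(n - below_nht) / n,
        frac_below_rr=below_rr / n,
        frac_within_rr=(n - below_rr - above_rr) / n,
        frac_above_rr=above_rr / n,
    )


def microstructure_summary(profile: ThresholdProfile) -> MicrostructureSummary:
    """Depth (max − min threshold) and extrema locations for one profile.

    Ties among maxima or minima resolve to the lowest frequency. Extrema
    offsets relative to the matched percept frequency are reported only when
    the profile carries one.
    """
    if len(profile.frequencies) < 2:
        raise ValueError("need at least 2 frequencies for microstructure")
    t = profile.thresholds
    i_max = int(np.argmax(t))  # first occurrence = lowest frequency
    i_min = int(np.argmin(t))
    f_max = float(profile.frequencies[i_max])
    f_min = float(profile.frequencies[i_min])
    return MicrostructureSummary(
        depth=float(t[i_max] - t[i_min]),
        max_frequency=f_max,
        min_frequency=f_min,
        max_offset_from_spf=None if profile.spf is None else f_max - profile.spf,
        min_offset_from_spf=None if profile.spf is None else f_min - profile.spf,
    )


def rank_sum_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: Literal["auto", "exact", "normal"] = "auto",
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Mid-ranks are assigned to ties. The z statistic always uses the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction toward the null mean. The p-value uses exact enumeration over
    all rank assignments for small samples (``n1 + n2 <= 10`` under
    ``"auto"``) and the normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined, method="average")
    w = float(np.sum(ranks[:n1]))
    mean_w = n1 * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        z = 0.0
        p = 1.0
    else:
        d = w - mean_w
        # continuity correction shrinks |d| by 0.5
        d_cc = d - 0.5 * np.sign(d) if d != 0 else 0.0
        z = d_cc / math.sqrt(var_w)
        if method == "exact" or (method == "auto" and n <= 10):
            from itertools import combinations

            ws = np.fromiter(
                (ranks[list(idx)].sum() for idx in combinations(range(n), n1)),
                dtype=float,
            )
            p = float(np.mean(np.abs(ws - mean_w) >= abs(d) - 1e-9))
        else:
            p = 2.0 * stats.norm.sf(abs(z))
    return RankSumResult(
        rank_sum=w,
        rank_sum_b=float(n * (n + 1) / 2.0 - w),
        z_value=float(z),
        p_value=float(min(p, 1.0)),
    )


def ks_two_sample(sample_a: Sequence[float], sample_b: Sequence[float]) -> KsResult:
    """Two-sample Kolmogorov–Smirnov test (asymptotic two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp", alternative="two-sided")
    return KsResult(d_statistic=float(res.statistic), p_value=float(res.pvalue))


def summarize_spf(spfs: Sequence[float]) -> tuple[float, list[float]]:
    """Median matched percept frequency after excluding unreliable entries.

    Entries below 15 Hz are flagged invalid and excluded; returns the median
    of the remainder and the list of excluded values.
    """
    vals = np.asarray(spfs, dtype=float)
    excluded = [float(v) for v in vals[vals < MIN_VALID_SPF_HZ]]
    kept = vals[vals >= MIN_VALID_SPF_HZ]
    if len(kept) == 0:
        raise ValueError("no valid percept frequencies after exclusion")
    return float(np.median(kept)), excluded
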