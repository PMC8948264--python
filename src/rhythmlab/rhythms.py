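"""Rhythm statistics for binned locomotor-activity records.

The central object is the :class:`ActivityTrace`: event counts (wheel
revolutions or infrared beam crosses) per fixed-width time bin for one
subject.  On top of it this module provides

* the Sokolove–Bushell chi-squared periodogram,
* FFT relative power as a rhythm-strength index,
* threshold-based activity onset/offset detection,
* regression-based period estimation from daily onsets,
* phase-shift and phase-angle-of-entrainment measures,
* mean daily activity.

Conventions (declared, since actigraphy packages differ):

* Periodogram statistic Q_P = K * N_used * sum_h (M_h - M)^2 / sum_i (x_i - M)^2
  over K complete folds of P bins (trailing partial cycle discarded), so that
  Q_P ~ chi2(P_bins - 1) under white noise.
* "Periodogram amplitude" = Q at the main peak minus the significance line
  at that period.
* "FFT power" = maximum of the spectrum normalized to unit total power over
  positive frequencies, within a circadian band (default 18-30 h); a 0.01
  rhythmicity threshold is meaningful on this scale.
* Onset = first bin (after centered moving-average smoothing) at or above
  20% of the cycle maximum; offset = last bin at or above 5%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import LightSchedule

__all__ = [
    "ActivityTrace",
    "PeriodogramResult",
    "SpectralPower",
    "OnsetSeries",
    "RegressionFit",
    "DegenerateTraceError",
    "chi_square_periodogram",
    "fft_relative_power",
    "detect_onsets",
    "onset_regression",
    "phase_shift_from_pulse",
    "phase_angle_of_entrainment",
    "mean_daily_activity",
    "free_running_period",
]


class DegenerateTraceError(ValueError):
    """Trace cannot support the requested statistic (e.g. zero variance)."""


@dataclass
class ActivityTrace:
    """Binned event counts for one subject.

    Parameters
    ----------
    subject_id : str
    species : str
        ``"mouse"`` (wheel revolutions, typically 6-min bins) or ``"fly"``
        (beam crosses, 1-min bins).
    bin_minutes : float
        Bin width in minutes.
    start : float
        Hour (on the schedule time axis) of the first bin's left edge.
    counts : ndarray of int
        Non-negative event counts, one per bin.
    """

    subject_id: str
    species: str
    bin_minutes: float
    start: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_minutes <= 0:
            raise ValueError("bin_minutes must be positive")

    @property
    def bin_hours(self) -> float:
        return self.bin_minutes / 60.0

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def duration_hours(self) -> float:
        return self.n_bins * self.bin_hours

    def bin_starts(self) -> np.ndarray:
        return self.start + self.bin_hours * np.arange(self.n_bins)

    def slice_hours(self, t0: float, t1: float) -> "ActivityTrace":
        """Sub-trace covering schedule hours [t0, t1)."""
        i0 = int(round((t0 - self.start) / self.bin_hours))
        i1 = int(round((t1 - self.start) / self.bin_hours))
        if i0 < 0 or i1 > self.n_bins or i1 <= i0:
            raise ValueError(
                f"window [{t0}, {t1}) outside trace span "
                f"[{self.start}, {self.start + self.duration_hours})"
            )
        return dataclasses.replace(self, start=self.start + i0 * self.bin_hours,
                                   counts=self.counts[i0:i1])

    def rebin(self, bin_minutes: float) -> "ActivityTrace":
        """Aggregate counts into wider bins (must be an integer multiple)."""
        f = bin_minutes / self.bin_minutes
        if abs(f - round(f)) > 1e-9 or f < 1:
            raise ValueError("new bin width must be an integer multiple of the old")
        f = int(round(f))
        n = (self.n_bins // f) * f
        counts = self.counts[:n].reshape(-1, f).sum(axis=1)
        return dataclasses.replace(self, bin_minutes=bin_minutes, counts=counts)


# ---------------------------------------------------------------------------
# chi-squared periodogram
# ---------------------------------------------------------------------------

@dataclass
class PeriodogramResult:
    periods: np.ndarray          # candidate periods, hours
    Q: np.ndarray                # statistic per period
    dof: np.ndarray              # P_bins - 1 per period
    sig_line: np.ndarray         # significance threshold per period
    alpha: float
    peaks: list[tuple[float, float, float]]  # (period, Q, Q - sig), by excess desc

    @property
    def peak_period(self) -> float | None:
        return self.peaks[0][0] if self.peaks else None

    @property
    def amplitude(self) -> float | None:
        """Q minus the significance line at the main peak."""
        return self.peaks[0][2] if self.peaks else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period_h": self.periods, "Q": self.Q,
                             "dof": self.dof, "sig_line": self.sig_line})


def chi_square_periodogram(trace: ActivityTrace, min_period: float = 16.0,
                           max_period: float = 28.0, alpha: float = 0.05,
                           bonferroni: bool = False) -> PeriodogramResult:
    """Sokolove–Bushell chi-squared periodogram.

    Candidate periods are integer multiples of the bin width between
    ``min_period`` and ``max_period``.  For each candidate of ``P`` bins the
    trace is folded into ``K = N // P`` complete cycles (the trailing partial
    cycle is discarded) and

        Q_P = K * N_used * sum_h (M_h - M)^2 / sum_i (x_i - M)^2,

    with ``M_h`` the mean of fold column ``h`` and ``M`` the grand mean of
    the ``N_used = K * P`` bins used.  Under white noise Q_P ~ chi2(P - 1);
    the significance line is the (1 - alpha) quantile of that distribution
    (optionally Bonferroni-corrected over the number of tested periods).
    Peaks are local maxima of Q above the line, ordered by excess Q.
    """
    x = np.asarray(trace.counts, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateTraceError("zero-variance trace has no periodogram")
    bh = trace.bin_hours
    p_lo = int(np.ceil(min_period / bh - 1e-9))
    p_hi = int(np.floor(max_period / bh + 1e-9))
    if p_hi < p_lo:
        raise ValueError("period range narrower than one bin step")
    if trace.duration_hours < 3 * max_period:
        raise ValueError("trace must cover at least 3 * max_period")

    p_bins = np.arange(p_lo, p_hi + 1)
    Q = np.empty(p_bins.size)
    for j, P in enumerate(p_bins):
        K = x.size // P
        n_used = K * P
        xs = x[:n_used]
        m = xs.mean()
        col_means = xs.reshape(K, P).mean(axis=0)
        denom = ((xs - m) ** 2).sum()
        Q[j] = K * n_used * ((col_means - m) ** 2).sum() / denom

    dof = p_bins - 1
    a = alpha / p_bins.size if bonferroni else alpha
    sig = stats.chi2.ppf(1.0 - a, dof)
    periods = p_bins * bh

    above = Q > sig
    peaks = []
    for j in range(Q.size):
        if not above[j]:
            continue
        left = Q[j - 1] if j > 0 else -np.inf
        right = Q[j + 1] if j < Q.size - 1 else -np.inf
        if Q[j] >= left and Q[j] > right:
            peaks.append((float(periods[j]), float(Q[j]), float(Q[j] - sig[j])))
    peaks.sort(key=lambda t: -t[2])
    return PeriodogramResult(periods, Q, dof, sig, alpha, peaks)


# ---------------------------------------------------------------------------
# FFT rhythm strength
# ---------------------------------------------------------------------------

@dataclass
class SpectralPower:
    frequencies: np.ndarray       # cycles per hour (positive frequencies)
    normalized_power: np.ndarray  # sums to 1 over positive frequencies
    band: tuple[float, float]     # (min_period, max_period), hours
    rhythm_power: float           # max normalized power within band
    constant_trace: bool = False


def fft_relative_power(trace: ActivityTrace,
                       band: tuple[float, float] = (18.0, 30.0)) -> SpectralPower:
    """Fraction of spectral power at the dominant circadian-band frequency.

    The mean-subtracted counts are Fourier-transformed (no taper); power is
    normalized to sum to one over positive frequencies, and ``rhythm_power``
    is the maximum normalized power at periods inside ``band``.  A constant
    trace yields 0 with ``constant_trace=True``.
    """
    if trace.duration_hours < 48.0:
        raise ValueError("trace must cover at least 2 days")
    x = np.asarray(trace.counts, dtype=float)
    x = x - x.mean()
    if np.all(x == 0):
        return SpectralPower(np.empty(0), np.empty(0), band, 0.0, True)
    spec = np.abs(np.fft.rfft(x)[1:]) ** 2  # drop DC
    freqs = np.fft.rfftfreq(x.size, d=trace.bin_hours)[1:]
    power = spec / spec.sum()
    with np.errstate(divide="ignore"):
        periods = 1.0 / freqs
    in_band = (periods >= band[0]) & (periods <= band[1])
    rp = float(power[in_band].max()) if in_band.any() else 0.0
    return SpectralPower(freqs, power, band, rp)


# ---------------------------------------------------------------------------
# onset/offset detection and regression period
# ---------------------------------------------------------------------------

@dataclass
class OnsetSeries:
    """Detected activity onsets/offsets, one entry per cycle with activity.

    ``onsets`` and ``offsets`` are absolute hours on the schedule time axis;
    ``days`` are the corresponding cycle indices (0-based, cycles of
    ``folding_period`` hours counted from ``cycle_start``).
    """

    days: np.ndarray
    onsets: np.ndarray
    offsets: np.ndarray
    folding_period: float
    cycle_start: float
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.days.size

    def phases(self) -> np.ndarray:
        """Onset time within each cycle, hours in [0, folding_period)."""
        return self.onsets - self.cycle_start - self.days * self.folding_period

    def select_days(self, lo: int, hi: int) -> "OnsetSeries":
        """Entries with lo <= day < hi."""
        m = (self.days >= lo) & (self.days < hi)
        return OnsetSeries(self.days[m], self.onsets[m], self.offsets[m],
                           self.folding_period, self.cycle_start, self.params)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "onset_h": self.onsets,
                             "offset_h": self.offsets})


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    if w % 2 == 0:
        w += 1  # centered window
    pad = w // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(xp, kernel, mode="valid")


def _rest_phase(trace: ActivityTrace, period: float) -> float:
    """Phase (hours into the cycle) of minimum folded activity.

    Used to place detection windows so that each cycle window starts at the
    expected rest phase and the activity bout falls in its interior.
    """
    bh = trace.bin_hours
    P = max(1, int(round(period / bh)))
    K = trace.n_bins // P
    if K < 1:
        return 0.0
    prof = np.asarray(trace.counts[: K * P], float).reshape(K, P).mean(axis=0)
    w = max(1, int(round(3.0 / bh)))  # 3-h circular smoothing
    kernel = np.ones(w) / w
    sm = np.convolve(np.r_[prof, prof, prof], kernel, mode="same")[P:2 * P]
    return float(np.argmin(sm) * bh)


def detect_onsets(trace: ActivityTrace, folding_period: float = 24.0,
                  onset_frac: float = 0.20, offset_frac: float = 0.05,
                  smooth_minutes: float | None = None,
                  cycle_start: float | str | None = None) -> OnsetSeries:
    """Detect activity onset and offset in each folding-period cycle.

    Within each complete cycle window, after centered moving-average
    smoothing, the onset is the first bin whose smoothed value reaches
    ``onset_frac`` of the cycle maximum and the offset the last bin reaching
    ``offset_frac`` of it.  Cycles with no activity yield no entry.  The
    default smoothing is 15 min for mouse traces and 30 min for fly 1-min
    traces; thresholds are relative, so detection is invariant to a global
    rescaling of the counts.
    """
    if trace.duration_hours < 2 * folding_period:
        raise ValueError("need at least two cycles to detect onsets")
    if smooth_minutes is None:
        smooth_minutes = 30.0 if trace.species == "fly" else 15.0
    w = max(1, int(round(smooth_minutes / trace.bin_minutes)))
    sm = _moving_average(np.asarray(trace.counts, float), w)
    if cycle_start == "rest":
        cycle_start = trace.start + _rest_phase(trace, folding_period)
    elif cycle_start is None:
        cycle_start = trace.start
    bh = trace.bin_hours
    bins_per_cycle = folding_period / bh
    days, onsets, offsets = [], [], []
    d = 0
    while True:
        i0 = int(round((cycle_start + d * folding_period - trace.start) / bh))
        i1 = int(round((cycle_start + (d + 1) * folding_period - trace.start) / bh))
        if i1 > trace.n_bins:
            break
        if i0 >= 0:
            seg = sm[i0:i1]
            peak = seg.max()
            if peak > 0:
                on_idx = int(np.argmax(seg >= onset_frac * peak))
                off_idx = int(len(seg) - 1 - np.argmax(seg[::-1] >= offset_frac * peak))
                days.append(d)
                onsets.append(trace.start + (i0 + on_idx) * bh)
                offsets.append(trace.start + (i0 + off_idx) * bh)
        d += 1
    return OnsetSeries(np.asarray(days, int), np.asarray(onsets, float),
                       np.asarray(offsets, float), folding_period, cycle_start,
                       {"onset_frac": onset_frac, "offset_frac": offset_frac,
                        "smooth_minutes": smooth_minutes,
                        "bins_per_cycle": bins_per_cycle})


@dataclass
class RegressionFit:
    slope: float            # hours/day of onset drift at the folding period
    intercept: float        # hours, onset phase at day 0
    r2: float
    n_days: int
    implied_period: float   # folding_period + slope

    def predict(self, day: float) -> float:
        return self.intercept + self.slope * day


def _unwrap_phases(days: np.ndarray, phases: np.ndarray, period: float) -> np.ndarray:
    """Map successive phase differences into (-period/2, period/2] and accumulate."""
    out = np.empty_like(phases)
    out[0] = phases[0]
    for i in range(1, phases.size):
        d = phases[i] - phases[i - 1]
        d -= period * np.floor(d / period + 0.5)
        out[i] = out[i - 1] + d
    return out


def onset_regression(onsets: OnsetSeries, day_range: tuple[int, int] | None = None,
                     folding_period: float | None = None) -> RegressionFit:
    """Free-running period from a regression line through daily onsets.

    Onset phases are unwrapped (successive differences mapped to
    ``(-T/2, T/2]``) and regressed on day by ordinary least squares; the
    implied period is the folding period plus the fitted slope.
    """
    T = folding_period if folding_period is not None else onsets.folding_period
    sel = onsets if day_range is None else onsets.select_days(*day_range)
    if len(sel) < 3:
        raise ValueError(f"need >= 3 onsets for a regression, have {len(sel)}")
    y = _unwrap_phases(sel.days, sel.phases(), T)
    fit = stats.linregress(sel.days, y)
    return RegressionFit(float(fit.slope), float(fit.intercept),
                         float(fit.rvalue ** 2), len(sel), T + float(fit.slope))


def phase_shift_from_pulse(onsets: OnsetSeries, pulse_day: int,
                           pre_days: int = 10, post_days: int = 10,
                           transient_skip: int = 3) -> float:
    """Phase shift from extended regression lines before and after a pulse.

    Regression lines are fitted to the onsets of the ``pre_days`` days before
    ``pulse_day`` and to ``post_days`` days starting ``transient_skip`` days
    after it; both lines are extrapolated to the day after the pulse and the
    shift is (pre-line onset) - (post-line onset): positive = advance
    (activity starts earlier), negative = delay.
    """
    T = onsets.folding_period
    all_unwrapped = _unwrap_phases(onsets.days, onsets.phases(), T)
    pre_m = (onsets.days >= pulse_day - pre_days) & (onsets.days < pulse_day)
    post_m = ((onsets.days >= pulse_day + transient_skip)
              & (onsets.days < pulse_day + transient_skip + post_days))
    if pre_m.sum() < 3 or post_m.sum() < 3:
        raise ValueError("insufficient onsets on one side of the pulse")
    pre = stats.linregress(onsets.days[pre_m], all_unwrapped[pre_m])
    post = stats.linregress(onsets.days[post_m], all_unwrapped[post_m])
    d_eval = pulse_day + 1
    return float((pre.intercept + pre.slope * d_eval)
                 - (post.intercept + post.slope * d_eval))


def phase_angle_of_entrainment(onsets: OnsetSeries, schedule: LightSchedule,
                               n_days: int = 6) -> float:
    """Mean signed difference (onset - lights-off) over the last n_days onsets.

    Negative values mean the activity onset precedes lights-off.  Requires
    ``n_days`` consecutive detected onsets under a periodic light schedule.
    """
    if len(onsets) < n_days:
        raise ValueError(f"need {n_days} onsets, have {len(onsets)}")
    days = onsets.days[-n_days:]
    if np.any(np.diff(days) != 1):
        raise ValueError("missing onsets inside the phase-angle window")
    off = schedule.lights_off_times()
    if off.size == 0:
        raise ValueError("schedule has no lights-off transitions")
    angles = []
    for t in onsets.onsets[-n_days:]:
        angles.append(t - off[np.argmin(np.abs(off - t))])
    return float(np.mean(angles))


def mean_daily_activity(trace: ActivityTrace, n_days: int, start_day: int = 0,
                        day_length: float = 24.0) -> float:
    """Average daily event count over ``n_days`` consecutive days."""
    t0 = trace.start + start_day * day_length
    sub = trace.slice_hours(t0, t0 + n_days * day_length)
    return float(sub.counts.sum() / n_days)


def free_running_period(trace: ActivityTrace, scan: tuple[float, float] = (16.0, 28.0),
                        alpha: float = 0.05, **onset_kw) -> RegressionFit:
    """Free-running period via the onset-regression route.

    The periodogram peak provides the folding period; onsets are then
    detected in cycle windows anchored at the rest phase of the folded
    profile and regressed on day, so the implied period refines the peak by
    the residual onset drift.  Raises if the periodogram has no significant
    peak.
    """
    pg = chi_square_periodogram(trace, scan[0], scan[1], alpha=alpha)
    if pg.peak_period is None:
        raise DegenerateTraceError("no significant periodogram peak in scan range")
    onsets = detect_onsets(trace, folding_period=pg.peak_period,
                           cycle_start="rest", **onset_kw)
    return onset_regression(onsets)
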