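"""Higher-level behavioral endpoints.

Jetlag re-entrainment kinetics, light-transition anticipation indices,
rhythmicity and internal-desynchrony classification, group activity
profiles, and the Pearson chi-squared test used to compare category
distributions between genotypes.

Classification rules
--------------------
Fly under constant darkness (12-day segment, two 6-day windows):
a window is *rhythmic* when the chi-squared periodogram shows a significant
peak and the FFT relative power exceeds 0.01.  Labels: ``rhythmic`` (both
windows, and the peak period is stable across sliding 6-day windows),
``delayed_arrhythmic`` (first window only), ``arrhythmic`` (neither),
``rhythmic_unstable_period`` (both windows but the sliding-window period SD
exceeds a threshold, 0.5 h by default).

Mouse under chronic jetlag (6-h advance every 2 days; effective Zeitgeber
period 21 h): a significant periodogram peak in the short band (20-22 h)
marks an entrained component; an additional significant peak in the long
band (22.5-28 h) marks internal desynchrony, subtyped by whether the long
component runs longer (``desynchronized``) or shorter
(``desynchronized_short_period``) than 24 h.  No significant peak at all is
``arrhythmic``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rhythms import (ActivityTrace, OnsetSeries, chi_square_periodogram,
                      fft_relative_power)
from .schedule import LightSchedule

__all__ = [
    "ReentrainmentResult",
    "AnticipationIndices",
    "RhythmClass",
    "daily_phase_shifts",
    "days_to_reentrain",
    "anticipation_indices",
    "relative_activity_profile",
    "classify_fly_dd",
    "classify_chronic_jetlag",
    "category_table_test",
]


# ---------------------------------------------------------------------------
# jetlag re-entrainment
# ---------------------------------------------------------------------------

@dataclass
class ReentrainmentResult:
    """Cumulative daily phase shifts after a schedule shift.

    ``daily_shift[i]`` is the cumulative shift (hours, positive toward the
    direction of the schedule shift) on post-shift day ``post_days[i]``
    (1-based).  ``total_shift`` is the magnitude of the schedule shift and
    ``direction`` +1 for an advance, -1 for a delay.
    """

    post_days: np.ndarray
    daily_shift: np.ndarray
    total_shift: float
    direction: int
    days_to_entrain: int | None = None
    criterion: tuple[float, int] | None = None

    @property
    def never_entrained(self) -> bool:
        return self.days_to_entrain is None and self.criterion is not None


def _detect_schedule_shift(schedule: LightSchedule) -> tuple[float, float, int]:
    """Time, magnitude and direction of the single abrupt shift in a schedule."""
    off = schedule.lights_off_times()
    d = np.diff(off)
    anom = np.where(np.abs(d - 24.0) > 0.5)[0]
    if anom.size != 1:
        raise ValueError("schedule does not contain exactly one abrupt shift")
    i = anom[0]
    shift = 24.0 - d[i]          # positive = advance
    # the shift "happens" between the last old-pattern and the first
    # new-pattern lights-off
    t_shift = 0.5 * (off[i] + off[i + 1])
    return float(t_shift), abs(float(shift)), int(np.sign(shift))


def daily_phase_shifts(onsets: OnsetSeries, schedule: LightSchedule,
                       shift_day: int | None = None, baseline_days: int = 6,
                       old_period: float = 24.0) -> ReentrainmentResult:
    """Cumulative re-entrainment curve after an acute schedule shift.

    Each post-shift onset is expressed as a phase relative to the *old*
    (pre-shift) schedule; the cumulative shift on day ``d`` is the baseline
    mean phase (last ``baseline_days`` pre-shift days) minus the phase on
    day ``d``, signed positive toward the direction of the shift.
    """
    t_shift, total, direction = _detect_schedule_shift(schedule)
    if shift_day is None:
        shift_day = int(np.ceil((t_shift - onsets.cycle_start) / old_period - 1e-9))
    phases = onsets.onsets - onsets.days * old_period  # old-schedule reference
    pre = (onsets.days < shift_day) & (onsets.days >= shift_day - baseline_days)
    if pre.sum() == 0:
        raise ValueError("no pre-shift baseline onsets available")
    baseline = float(phases[pre].mean())
    post = onsets.days >= shift_day
    cumulative = direction * (baseline - phases[post])
    return ReentrainmentResult(onsets.days[post] - shift_day + 1,
                               np.asarray(cumulative, float), total, direction)


def days_to_reentrain(result: ReentrainmentResult, total_shift: float | None = None,
                      tolerance: float = 0.5, consecutive: int = 3) -> int | None:
    """First post-shift day on which the cumulative shift has stabilized.

    Stability = within ``tolerance`` hours of the full shift for
    ``consecutive`` consecutive recorded days.  Returns ``None`` (and flags
    the result never-entrained) when the criterion is never met.
    """
    total = result.total_shift if total_shift is None else total_shift
    ok = np.abs(result.daily_shift - total) <= tolerance
    result.criterion = (tolerance, consecutive)
    for i in range(len(ok)):
        if i + consecutive <= len(ok) and ok[i:i + consecutive].all():
            result.days_to_entrain = int(result.post_days[i])
            return result.days_to_entrain
    result.days_to_entrain = None
    return None


# ---------------------------------------------------------------------------
# anticipation and activity profiles
# ---------------------------------------------------------------------------

@dataclass
class AnticipationIndices:
    """Morning/evening anticipation: 3-h pre-transition activity over 6-h.

    0.5 is the no-anticipation null; values significantly above 0.5 indicate
    anticipatory behavior.  An index is NaN (and flagged undefined) when the
    6-h denominator window holds no activity.
    """

    morning_AI: float
    evening_AI: float
    window_days: int
    morning_defined: bool = True
    evening_defined: bool = True


def _window_sum(traces: list[ActivityTrace], t0: float, t1: float) -> float:
    total = 0.0
    for tr in traces:
        starts = tr.bin_starts()
        m = (starts >= t0 - 1e-9) & (starts < t1 - 1e-9)
        total += float(tr.counts[m].sum())
    return total


def anticipation_indices(traces: list[ActivityTrace], schedule: LightSchedule,
                         last_n_days: int = 3) -> AnticipationIndices:
    """Anticipation indices pooled over subjects and the last n LD days.

    Morning AI = activity in the 3 h preceding lights-on / activity in the
    6 h preceding lights-on; evening AI likewise for lights-off.
    """
    ons = schedule.lights_on_times()
    offs = schedule.lights_off_times()
    if ons.size < last_n_days or offs.size < last_n_days:
        raise ValueError(f"schedule has fewer than {last_n_days} LD cycles")
    out = {}
    for name, events in (("morning", ons[-last_n_days:]),
                         ("evening", offs[-last_n_days:])):
        num = den = 0.0
        for e in events:
            num += _window_sum(traces, e - 3.0, e)
            den += _window_sum(traces, e - 6.0, e)
        out[name] = (num / den if den > 0 else np.nan, den > 0)
    return AnticipationIndices(out["morning"][0], out["evening"][0], last_n_days,
                               out["morning"][1], out["evening"][1])


def relative_activity_profile(traces: list[ActivityTrace], schedule: LightSchedule,
                              last_n_days: int = 3) -> np.ndarray:
    """Group-mean hourly activity profile normalized to its maximum.

    Each subject's activity over the last ``last_n_days`` LD cycles is
    averaged minute-by-minute across days, aggregated to 1-h Zeitgeber-time
    bins, averaged across subjects, and divided by the group maximum (peak
    value exactly 1).  Hour 0 is lights-on.
    """
    if not traces:
        raise ValueError("empty group")
    ons = schedule.lights_on_times()
    if ons.size < last_n_days:
        raise ValueError(f"schedule has fewer than {last_n_days} LD cycles")
    profiles = []
    for tr in traces:
        per_day = []
        for t_on in ons[-last_n_days:]:
            day = tr.slice_hours(t_on, t_on + 24.0)
            hourly = day.rebin(60.0)
            per_day.append(hourly.counts[:24])
        profiles.append(np.mean(per_day, axis=0))
    group = np.mean(profiles, axis=0)
    peak = group.max()
    if peak == 0:
        raise ValueError("group shows no activity in the profile window")
    return group / peak


# ---------------------------------------------------------------------------
# rhythm classification
# ---------------------------------------------------------------------------

@dataclass
class RhythmClass:
    label: str
    evidence: dict = field(default_factory=dict)


def _daily_period_sd(trace: ActivityTrace, fold: float) -> float:
    """SD of day-to-day period estimates from per-cycle profile phases.

    Each fold-length cycle's profile is circularly cross-correlated with the
    mean folded profile; the lag of maximum correlation is that cycle's
    phase.  Successive phase differences (wrapped to half a cycle) estimate
    the daily period deviation from ``fold``; their SD measures period
    stability.
    """
    bh = trace.bin_hours
    P = int(round(fold / bh))
    K = trace.n_bins // P
    if K < 4:
        return 0.0
    x = np.asarray(trace.counts[:K * P], float).reshape(K, P)
    x = x - x.mean(axis=1, keepdims=True)
    m = x.mean(axis=0)
    fm = np.conj(np.fft.rfft(m))
    lags = []
    for k in range(K):
        c = np.fft.irfft(np.fft.rfft(x[k]) * fm, n=P)
        lag = float(np.argmax(c)) * bh
        if lag > fold / 2:
            lag -= fold
        lags.append(lag)
    d = np.diff(lags)
    d -= fold * np.floor(d / fold + 0.5)  # wrap to (-fold/2, fold/2]
    return float(np.std(d, ddof=1)) if d.size >= 3 else 0.0


def _window_rhythmic(trace: ActivityTrace, scan: tuple[float, float], alpha: float,
                     fft_threshold: float, band: tuple[float, float]):
    pg = chi_square_periodogram(trace, scan[0], scan[1], alpha=alpha)
    power = fft_relative_power(trace, band=band).rhythm_power
    rhythmic = pg.peak_period is not None and power > fft_threshold
    return rhythmic, pg.peak_period, power


def classify_fly_dd(trace: ActivityTrace, week1: tuple[int, int] = (1, 6),
                    week2: tuple[int, int] = (7, 12), fft_threshold: float = 0.01,
                    alpha: float = 0.05, period_sd_threshold: float = 0.5,
                    scan: tuple[float, float] = (16.0, 28.0),
                    band: tuple[float, float] = (18.0, 30.0),
                    analysis_bin_minutes: float = 6.0,
                    interval_sd_threshold: float = 0.5) -> RhythmClass:
    """Classify a fly's DD behavior from two 6-day windows.

    ``week1``/``week2`` are 1-based inclusive day ranges relative to the
    trace start.  1-min traces are re-binned (default 6 min) for the
    periodogram; the FFT rhythm-strength criterion uses the same windows.

    A fly rhythmic in both windows is called unstable when either the peak
    period's SD across sliding 6-day windows exceeds
    ``period_sd_threshold`` or the SD of day-to-day period estimates —
    successive differences of daily phases obtained by circularly
    cross-correlating each cycle's activity profile with the mean folded
    profile — exceeds ``interval_sd_threshold`` (windowed period estimates
    average several days of drift, so cycle-level phases are the more
    sensitive witness of a fluctuating period).
    """
    need_days = week2[1]
    if trace.duration_hours < need_days * 24.0:
        raise ValueError(f"DD segment must cover {need_days} days")
    if trace.bin_minutes < analysis_bin_minutes:
        trace = trace.rebin(analysis_bin_minutes)

    def window(days: tuple[int, int]) -> ActivityTrace:
        t0 = trace.start + (days[0] - 1) * 24.0
        return trace.slice_hours(t0, trace.start + days[1] * 24.0)

    try:
        r1, p1, f1 = _window_rhythmic(window(week1), scan, alpha, fft_threshold, band)
    except Exception:
        r1, p1, f1 = False, None, 0.0
    try:
        r2, p2, f2 = _window_rhythmic(window(week2), scan, alpha, fft_threshold, band)
    except Exception:
        r2, p2, f2 = False, None, 0.0

    # sliding 6-day windows for period stability
    sliding = []
    for d0 in range(1, need_days - 5):
        try:
            pg = chi_square_periodogram(window((d0, d0 + 5)), scan[0], scan[1],
                                        alpha=alpha)
        except Exception:
            continue
        if pg.peak_period is not None:
            sliding.append(pg.peak_period)
    period_sd = float(np.std(sliding)) if len(sliding) >= 2 else 0.0

    # cycle-level daily-period variability over the full segment
    interval_sd = 0.0
    if r1 and r2:
        fold = p1 if p1 is not None else 24.0
        seg = window((week1[0], week2[1]))
        interval_sd = _daily_period_sd(seg, fold)

    unstable = (period_sd > period_sd_threshold
                or interval_sd > interval_sd_threshold)
    if r1 and r2:
        label = "rhythmic_unstable_period" if unstable else "rhythmic"
    elif r1 and not r2:
        label = "delayed_arrhythmic"
    elif not r1 and not r2:
        label = "arrhythmic"
    else:  # rhythmic only late: no category of its own; closest is unstable
        label = "rhythmic_unstable_period" if unstable else "delayed_arrhythmic"
    return RhythmClass(label, {"week1": (r1, p1, f1), "week2": (r2, p2, f2),
                               "period_sd": period_sd, "interval_sd": interval_sd,
                               "sliding_periods": sliding})


def classify_chronic_jetlag(trace: ActivityTrace, schedule: LightSchedule,
                            short_band: tuple[float, float] = (20.0, 22.0),
                            long_band: tuple[float, float] = (22.5, 28.0),
                            alpha: float = 0.05,
                            scan: tuple[float, float] = (16.0, 28.0),
                            split_at: float = 24.0,
                            min_prominence_frac: float = 0.10) -> RhythmClass:
    """Entrainment/desynchrony classification under chronic jetlag.

    Runs the periodogram over the jetlag segment of the schedule (the whole
    trace when the schedule defines no ``"jetlag"`` segment).  A band peak
    counts as a rhythmic component only when its excess over the
    significance line reaches ``min_prominence_frac`` of the largest peak's
    excess: a strongly periodic rhythm folded at rational multiples of its
    period throws small but formally significant subharmonic peaks, which
    must not be mistaken for a second oscillator.
    """
    if "jetlag" in schedule.segments:
        t0, t1 = schedule.segment_bounds("jetlag")
        t0 = max(t0, trace.start)
        t1 = min(t1, trace.start + trace.duration_hours)
        trace = trace.slice_hours(t0, t1)
    if trace.duration_hours < 21 * 24.0:
        raise ValueError("chronic-jetlag segment must cover at least 21 days")
    pg = chi_square_periodogram(trace, scan[0], scan[1], alpha=alpha)
    min_excess = min_prominence_frac * max((p[2] for p in pg.peaks), default=0.0)

    def best_in(band: tuple[float, float]):
        cands = [p for p in pg.peaks
                 if band[0] <= p[0] <= band[1] and p[2] >= min_excess]
        return max(cands, key=lambda t: t[2]) if cands else None

    short = best_in(short_band)
    long_ = best_in(long_band)
    ev = {"short_peak": short, "long_peak": long_, "n_peaks": len(pg.peaks)}
    if short is None and long_ is None:
        return RhythmClass("arrhythmic", ev)
    if long_ is None:
        return RhythmClass("entrained", ev)
    label = "desynchronized" if long_[0] > split_at else "desynchronized_short_period"
    return RhythmClass(label, ev)


# ---------------------------------------------------------------------------
# category-table chi-squared test
# ---------------------------------------------------------------------------

def category_table_test(table) -> tuple[float, int, float]:
    """Two-sided Pearson chi-squared test on a groups-by-categories table.

    No continuity correction is applied (this convention reproduces
    reference p values of behavioral category comparisons to their reported
    precision, which a Yates-corrected test does not).  Returns
    ``(chi2, dof, p)``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("table entries must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has an all-zero margin")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
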