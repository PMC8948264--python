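"""Light schedules for circadian behavioral experiments.

A :class:`LightSchedule` is a piecewise-constant light-intensity function of
time built from contiguous :class:`LightEpoch` blocks.  Time is real-valued
hours from an arbitrary origin placed at the first lights-on; all intervals
are half-open ``[start, end)`` so every instant belongs to exactly one bin.

Supported paradigms
-------------------
LD            standard light:dark cycle (default 12:12, 24-h cycle)
DD            constant darkness
LL            constant light
stepped_LL    constant light with a staircase of intensities
acute_jetlag  single abrupt advance or delay of the LD schedule
chronic_jetlag  repeated advances (e.g. 6-h advance every 2 days, the
              "ChrA 6/2" paradigm, whose effective Zeitgeber period is
              (48 - 6) / 2 = 21 h)

Jetlag advances are implemented by truncating the dark phase of the
transition night (lights-on arrives early); pass ``truncate="light"`` to
shorten the light phase instead.  Delays always extend the dark phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LightEpoch",
    "LightSchedule",
    "ScheduleError",
    "AperiodicEpochError",
    "build_schedule",
    "effective_zeitgeber_period",
]


class ScheduleError(ValueError):
    """Invalid schedule descriptor or parameters."""


class AperiodicEpochError(ScheduleError):
    """The requested segment has no defined Zeitgeber period."""


@dataclass(frozen=True)
class LightEpoch:
    """One homogeneous block of the light schedule.

    Parameters
    ----------
    start : float
        Hours since the experiment origin.
    duration : float
        Epoch length in hours.  May be shorter than ``cycle_length`` times an
        integer (a truncated final cycle implements jetlag transitions).
    cycle_length : float
        Hours per light cycle.
    photoperiod : float
        Hours of light per cycle (0 for DD, ``cycle_length`` for LL).
    lights_on_offset : float
        Hours into each cycle at which lights come on.
    intensity : float
        Light intensity in lux during the light phase.
    """

    start: float
    duration: float
    cycle_length: float = 24.0
    photoperiod: float = 12.0
    lights_on_offset: float = 0.0
    intensity: float = 40.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ScheduleError(f"epoch duration must be positive, got {self.duration}")
        if self.cycle_length <= 0:
            raise ScheduleError("cycle_length must be positive")
        if not 0.0 <= self.photoperiod <= self.cycle_length:
            raise ScheduleError("photoperiod must lie in [0, cycle_length]")
        if self.intensity < 0:
            raise ScheduleError("intensity must be non-negative")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def light_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Lux at time(s) ``t`` assuming t lies within this epoch."""
        if self.photoperiod == 0.0 or self.intensity == 0.0:
            return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
        phase = np.mod(np.asarray(t, dtype=float) - self.start, self.cycle_length)
        on = (phase >= self.lights_on_offset) & (
            phase < self.lights_on_offset + self.photoperiod
        )
        out = np.where(on, self.intensity, 0.0)
        return out if np.ndim(t) else float(out)

    def lights_on_times(self) -> np.ndarray:
        """Lights-on instants of every (possibly partial) cycle in the epoch."""
        if self.photoperiod == 0.0 or self.intensity == 0.0:
            return np.empty(0)
        n = int(np.ceil(self.duration / self.cycle_length))
        t = self.start + self.lights_on_offset + self.cycle_length * np.arange(n)
        return t[t < self.end - 1e-9]

    def lights_off_times(self) -> np.ndarray:
        t = self.lights_on_times() + self.photoperiod
        return np.minimum(t, self.end)


@dataclass
class LightSchedule:
    """Contiguous sequence of light epochs with named segments.

    ``segments`` maps a name (e.g. ``"baseline"``, ``"jetlag"``) to a
    ``(first_epoch_index, last_epoch_index_exclusive)`` pair; paradigm
    builders populate it so downstream analyses can address the relevant
    portion of the experiment without re-deriving transition times.
    """

    epochs: list[LightEpoch]
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)
    paradigm: str = "custom"

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ScheduleError("schedule needs at least one epoch")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise ScheduleError("epochs must be contiguous and non-overlapping")

    @property
    def start(self) -> float:
        return self.epochs[0].start

    @property
    def end(self) -> float:
        return self.epochs[-1].end

    @property
    def span(self) -> float:
        return self.end - self.start

    def _epoch_index(self, t: np.ndarray) -> np.ndarray:
        edges = np.array([e.start for e in self.epochs[1:]])
        return np.searchsorted(edges, t, side="right")

    def light_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Light intensity (lux) at time(s) ``t``; 0 outside the schedule."""
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(tt)
        inside = (tt >= self.start) & (tt < self.end)
        idx = self._epoch_index(tt[inside])
        vals = np.empty(inside.sum())
        for i, ep in enumerate(self.epochs):
            m = idx == i
            if m.any():
                vals[m] = ep.light_at(tt[inside][m])
        out[inside] = vals
        return out if np.ndim(t) else float(out[0])

    def segment_epochs(self, segment: str | int | None = None) -> list[LightEpoch]:
        if segment is None:
            return self.epochs
        if isinstance(segment, int):
            name = list(self.segments)[segment]
        else:
            name = segment
        if name not in self.segments:
            raise ScheduleError(f"unknown segment {name!r}; have {list(self.segments)}")
        i0, i1 = self.segments[name]
        return self.epochs[i0:i1]

    def segment_bounds(self, segment: str | int) -> tuple[float, float]:
        eps = self.segment_epochs(segment)
        return eps[0].start, eps[-1].end

    def lights_on_times(self, segment: str | int | None = None) -> np.ndarray:
        eps = self.segment_epochs(segment)
        return np.concatenate([e.lights_on_times() for e in eps] or [np.empty(0)])

    def lights_off_times(self, segment: str | int | None = None) -> np.ndarray:
        eps = self.segment_epochs(segment)
        return np.concatenate([e.lights_off_times() for e in eps] or [np.empty(0)])

    def transitions_table(self) -> pd.DataFrame:
        """Two-column export: cycle index and lights-off hour."""
        off = self.lights_off_times()
        return pd.DataFrame({"cycle": np.arange(len(off)), "lights_off_h": off})


# ---------------------------------------------------------------------------
# paradigm builders
# ---------------------------------------------------------------------------

def _ld_epochs(start: float, days: float, photoperiod: float, cycle_length: float,
               intensity: float) -> list[LightEpoch]:
    return [LightEpoch(start, days * cycle_length, cycle_length, photoperiod, 0.0,
                       intensity)]


def build_schedule(paradigm: str | dict, **params) -> LightSchedule:
    """Construct the light schedule for a named experimental paradigm.

    Parameters may also be passed as a single descriptor mapping with a
    ``"paradigm"`` key (the form used in pipeline config files).

    Paradigms and their keywords
    ----------------------------
    ``LD``:  days=14, photoperiod=12, cycle_length=24, intensity=40
    ``DD``:  days=14
    ``LL``:  days=14, intensity=40
    ``stepped_LL``: intensities=(5,10,20,40,80,120), dwell_days=14
    ``acute_jetlag``: direction="advance"|"delay", shift_hours=7,
        baseline_days=14, post_days=21, truncate="dark"|"light"
    ``chronic_jetlag``: advance_hours=6, every_n_days=2, days=28,
        baseline_days=0, truncate="dark"|"light"
    """
    if isinstance(paradigm, dict):
        params = {**paradigm, **params}
        paradigm = params.pop("paradigm")
    p = str(paradigm).lower()

    if p == "ld":
        days = params.pop("days", 14)
        pp = params.pop("photoperiod", 12.0)
        cl = params.pop("cycle_length", 24.0)
        lux = params.pop("intensity", 40.0)
        _no_extra(params)
        eps = _ld_epochs(0.0, days, pp, cl, lux)
        return LightSchedule(eps, {"LD": (0, 1)}, "LD")

    if p == "dd":
        days = params.pop("days", 14)
        _no_extra(params)
        eps = [LightEpoch(0.0, days * 24.0, 24.0, 0.0, 0.0, 0.0)]
        return LightSchedule(eps, {"DD": (0, 1)}, "DD")

    if p == "ll":
        days = params.pop("days", 14)
        lux = params.pop("intensity", 40.0)
        _no_extra(params)
        eps = [LightEpoch(0.0, days * 24.0, 24.0, 24.0, 0.0, lux)]
        return LightSchedule(eps, {"LL": (0, 1)}, "LL")

    if p == "stepped_ll":
        lux_steps = params.pop("intensities", (5.0, 10.0, 20.0, 40.0, 80.0, 120.0))
        dwell = params.pop("dwell_days", 14)
        _no_extra(params)
        eps, segs, t = [], {}, 0.0
        for i, lux in enumerate(lux_steps):
            eps.append(LightEpoch(t, dwell * 24.0, 24.0, 24.0, 0.0, float(lux)))
            segs[f"LL_{lux:g}lux"] = (i, i + 1)
            t += dwell * 24.0
        return LightSchedule(eps, segs, "stepped_LL")

    if p == "acute_jetlag":
        direction = params.pop("direction", "advance")
        shift = float(params.pop("shift_hours", 7.0))
        base_days = params.pop("baseline_days", 14)
        post_days = params.pop("post_days", 21)
        pp = params.pop("photoperiod", 12.0)
        lux = params.pop("intensity", 40.0)
        truncate = params.pop("truncate", "dark")
        _no_extra(params)
        if shift <= 0:
            raise ScheduleError("shift_hours must be positive")
        t_shift = base_days * 24.0
        if direction == "advance":
            if truncate == "dark":
                # lights-on of the first shifted day arrives `shift` hours
                # early: the last baseline night is cut short
                eps = [
                    LightEpoch(0.0, t_shift - shift, 24.0, pp, 0.0, lux),
                    LightEpoch(t_shift - shift, post_days * 24.0, 24.0, pp, 0.0, lux),
                ]
            elif truncate == "light":
                # last baseline day loses `shift` hours of light instead
                eps = [
                    LightEpoch(0.0, (base_days - 1) * 24.0, 24.0, pp, 0.0, lux),
                    LightEpoch((base_days - 1) * 24.0, 24.0 - shift, 24.0,
                               pp - shift, 0.0, lux),
                    LightEpoch(t_shift - shift, post_days * 24.0, 24.0, pp, 0.0, lux),
                ]
            else:
                raise ScheduleError(f"unknown truncate mode {truncate!r}")
        elif direction == "delay":
            # dark phase of the last baseline night extended by `shift` hours:
            # the transition cycle is one (24 + shift)-h cycle
            eps = [
                LightEpoch(0.0, (base_days - 1) * 24.0, 24.0, pp, 0.0, lux),
                LightEpoch((base_days - 1) * 24.0, 24.0 + shift, 24.0 + shift,
                           pp, 0.0, lux),
                LightEpoch(t_shift + shift, post_days * 24.0, 24.0, pp, 0.0, lux),
            ]
        else:
            raise ScheduleError(f"direction must be 'advance' or 'delay', got {direction!r}")
        n = len(eps)
        return LightSchedule(eps, {"baseline": (0, n - 1), "shifted": (n - 1, n)},
                             f"acute_jetlag_{direction}")

    if p == "chronic_jetlag":
        adv = float(params.pop("advance_hours", 6.0))
        every = int(params.pop("every_n_days", 2))
        days = params.pop("days", 28)
        base_days = params.pop("baseline_days", 0)
        pp = params.pop("photoperiod", 12.0)
        lux = params.pop("intensity", 40.0)
        truncate = params.pop("truncate", "dark")
        _no_extra(params)
        phase_budget = 24.0 - pp if truncate == "dark" else pp
        if adv == 0 or not abs(adv) < phase_budget:
            raise ScheduleError("advance_hours incompatible with photoperiod")
        if every < 1:
            raise ScheduleError("every_n_days must be >= 1")
        eps: list[LightEpoch] = []
        t = 0.0
        if base_days:
            eps.extend(_ld_epochs(0.0, base_days, pp, 24.0, lux))
            t = base_days * 24.0
        i0 = len(eps)
        block_h = every * 24.0 - adv
        n_blocks = int(np.ceil(days * 24.0 / block_h))
        for _ in range(n_blocks):
            # `every` cycles per block; the last cycle is `adv` hours shorter
            # (negative adv = a delay: the transition night is extended)
            if every > 1:
                eps.append(LightEpoch(t, (every - 1) * 24.0, 24.0, pp, 0.0, lux))
                t += (every - 1) * 24.0
            trans_len = 24.0 - adv
            if truncate == "dark" or adv < 0:
                eps.append(LightEpoch(t, trans_len, max(24.0, trans_len), pp, 0.0, lux))
            elif truncate == "light":
                eps.append(LightEpoch(t, trans_len, trans_len, pp - adv, 0.0, lux))
            else:
                raise ScheduleError(f"unknown truncate mode {truncate!r}")
            t += trans_len
        segs = {"jetlag": (i0, len(eps))}
        if base_days:
            segs = {"baseline": (0, i0), **segs}
        return LightSchedule(eps, segs, "chronic_jetlag")

    raise ScheduleError(f"unknown paradigm {paradigm!r}")


def _no_extra(params: dict) -> None:
    if params:
        raise ScheduleError(f"unknown schedule parameters: {sorted(params)}")


def effective_zeitgeber_period(schedule: LightSchedule,
                               segment: str | int | None = None) -> float:
    """Period of the repeating Zeitgeber block, in hours.

    For a schedule whose cycle lengths repeat in blocks (e.g. the chronic
    jetlag paradigm: 24, 18, 24, 18, ... h), this is the block duration
    divided by the number of cycles per block: (48 - 6) / 2 = 21 h for a
    6-h advance every 2 days.  Plain LD gives 24 h.  Raises
    :class:`AperiodicEpochError` when no cycle structure exists (DD/LL) or
    the cycle lengths do not repeat.
    """
    eps = schedule.segment_epochs(segment)
    cycles: list[float] = []
    for e in eps:
        if e.photoperiod == 0.0 or e.intensity == 0.0 or e.photoperiod == e.cycle_length:
            raise AperiodicEpochError("constant conditions have no Zeitgeber period")
        n_full = int(e.duration // e.cycle_length)
        cycles.extend([e.cycle_length] * n_full)
        rem = e.duration - n_full * e.cycle_length
        if rem > 1e-9:
            cycles.append(rem)  # truncated transition cycle
    if not cycles:
        raise AperiodicEpochError("segment contains no light cycles")
    arr = np.asarray(cycles)
    n = len(arr)
    for b in range(1, n + 1):
        if np.allclose(arr, arr[np.arange(n) % b], atol=1e-9):
            if b == n and n > 2 and not np.allclose(arr, arr[0], atol=1e-9):
                break  # no internal repetition: aperiodic
            return float(arr[:b].sum() / b)
    raise AperiodicEpochError("cycle lengths do not repeat; no defined Zeitgeber period")
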