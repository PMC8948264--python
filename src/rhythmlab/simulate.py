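"""Synthetic locomotor-activity and label-free proteomics data.

Behavioral generator
--------------------
Each subject carries one or two phase-only oscillator components.  A
component's activity onset advances by its intrinsic period tau each cycle
and, when a light cycle is present, receives a clamped daily correction
toward a Zeitgeber reference phase (lights-off for the nocturnal mouse,
lights-on for the fly morning component): the correction per cycle is at
most ``max_advance`` hours in the advancing direction and ``max_delay``
hours in the delaying direction, and is zero under constant conditions.
This is the simplest generator exhibiting bounded re-entrainment speed,
entrainment ranges, and internal desynchrony (a two-component mixture in
which only one component entrains).

Expected counts per bin are ``rate_rest + sum_k weight_k * rate_active_k *
W_k(t)``, multiplicatively suppressed by light according to ``masking``,
with ``W_k`` a boxcar over the alpha-hour active phase (mouse) or a bimodal
morning/evening waveform with exponential anticipation ramps (fly).  Counts
are independent Poisson draws per bin; everything is deterministic given
the seed (per-subject streams are derived from one master seed).

Proteome generator
------------------
Log2 LFQ intensities follow a per-protein baseline plus an optional group
effect and i.i.d. normal noise; cells go missing with a logistic
left-censoring probability (lower abundance => more missing); decoy,
contaminant and site-only rows are appended.  The ground-truth effect table
is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rhythms import ActivityTrace
from .schedule import LightSchedule

__all__ = [
    "OscillatorParams",
    "BehaviorSimConfig",
    "ProteomeSimConfig",
    "simulate_activity",
    "simulate_protein_table",
    "mouse_params",
    "fly_params",
]

TAU_BOUNDS = (16.0, 32.0)


@dataclass(frozen=True)
class OscillatorParams:
    """Generative parameters of one oscillator component.

    tau : intrinsic free-running period, hours (16 < tau < 32)
    phase0 : hour (schedule time axis) of the first activity onset
    alpha : active-phase duration, hours (mouse boxcar)
    rate_active : expected counts per bin at the active-phase peak
    rate_rest : expected counts per bin at rest
    max_advance / max_delay : largest daily phase correction toward the
        Zeitgeber in the advancing / delaying direction, hours per cycle
    entrained_angle : steady-state onset phase relative to the reference
        event, hours (negative = onset precedes it)
    masking : multiplicative suppression of activity by light, in [0, 1]
    amplitude_decay : per-day multiplicative decay of rate_active under
        constant darkness (1 = none)
    tau_drift_sd : per-day random-walk SD of tau, hours (0 = stable)

    Fly waveform parameters (ignored for the mouse boxcar): bout_halfwidth
    is the raised-cosine half-width of the morning/evening bouts,
    anticipation_amp and anticipation_tau_h shape the exponential ramp that
    precedes each bout, and evening_offset places the evening bout relative
    to the morning one.
    """

    tau: float = 23.6
    phase0: float = 12.0
    alpha: float = 9.0
    rate_active: float = 30.0
    rate_rest: float = 0.5
    max_advance: float = 2.0
    max_delay: float = 2.0
    entrained_angle: float = 0.0
    masking: float = 0.9
    amplitude_decay: float = 1.0
    tau_drift_sd: float = 0.0
    bout_halfwidth: float = 2.0
    anticipation_amp: float = 0.6
    anticipation_tau_h: float = 1.5
    evening_offset: float = 12.0
    morning_weight: float = 0.5

    def __post_init__(self) -> None:
        if not TAU_BOUNDS[0] < self.tau < TAU_BOUNDS[1]:
            raise ValueError(f"tau must lie in {TAU_BOUNDS}, got {self.tau}")
        if not 0 < self.alpha < self.tau:
            raise ValueError("alpha must lie in (0, tau)")
        if self.max_advance < 0 or self.max_delay < 0:
            raise ValueError("max_advance and max_delay must be >= 0")
        if not 0.0 <= self.masking <= 1.0:
            raise ValueError("masking must lie in [0, 1]")
        if self.rate_active < 0 or self.rate_rest < 0:
            raise ValueError("rates must be non-negative")


def mouse_params(**kw) -> OscillatorParams:
    """Mouse wheel-running defaults (nocturnal, tau ~23.6 h, strong masking)."""
    return OscillatorParams(**kw)


def fly_params(**kw) -> OscillatorParams:
    """Fly locomotor defaults (bimodal waveform, tau ~24 h, no masking)."""
    defaults = dict(tau=24.0, phase0=0.0, alpha=12.0, rate_active=2.0,
                    rate_rest=0.05, masking=0.0)
    defaults.update(kw)
    return OscillatorParams(**defaults)


@dataclass
class BehaviorSimConfig:
    """Cohort-level configuration for :func:`simulate_activity`."""

    species: str = "mouse"
    n_subjects: int = 10
    bin_minutes: float | None = None  # default: 6 (mouse) / 1 (fly)
    components: list[tuple[OscillatorParams, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "fly"):
            raise ValueError("species must be 'mouse' or 'fly'")
        if self.bin_minutes is None:
            self.bin_minutes = 6.0 if self.species == "mouse" else 1.0
        if 60.0 % self.bin_minutes > 1e-9:
            raise ValueError("bin_minutes must divide 60")
        if not self.components:
            base = mouse_params() if self.species == "mouse" else fly_params()
            self.components = [(base, 1.0)]
        w = np.array([w for _, w in self.components], dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be >= 0 and sum to 1")


def _reference_times(schedule: LightSchedule, event: str) -> np.ndarray:
    """Zeitgeber reference instants, only from epochs with a true light cycle."""
    times = []
    for ep in schedule.epochs:
        if ep.intensity <= 0 or ep.photoperiod <= 0 or ep.photoperiod >= ep.cycle_length:
            continue
        t = ep.lights_on_times() if event == "lights_on" else ep.lights_off_times()
        times.append(t)
    return np.concatenate(times) if times else np.empty(0)


def _component_onsets(p: OscillatorParams, refs: np.ndarray, span: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Cycle-by-cycle onset times and the tau value used at each step."""
    onsets = [p.phase0]
    tau = p.tau
    taus = [tau]
    t = p.phase0
    while t < span + tau:
        if p.tau_drift_sd > 0:
            tau = tau + rng.normal(0.0, p.tau_drift_sd)
            lo, hi = TAU_BOUNDS[0] + 0.5, TAU_BOUNDS[1] - 0.5
            if tau < lo:       # reflect the random walk back into range
                tau = 2 * lo - tau
            elif tau > hi:
                tau = 2 * hi - tau
        cand = t + tau
        s = 0.0
        if refs.size:
            targets = refs + p.entrained_angle
            j = int(np.argmin(np.abs(targets - cand)))
            delta = targets[j] - cand
            if abs(delta) <= tau / 2:  # a Zeitgeber cycle is present here
                # negative delta = onset must advance (move earlier)
                s = float(np.clip(delta, -p.max_advance, p.max_delay))
        t = cand + s
        onsets.append(t)
        taus.append(tau)
    return np.asarray(onsets), np.asarray(taus)


def _dd_days(schedule: LightSchedule, t: np.ndarray) -> np.ndarray:
    """Days spent in constant darkness at each time (0 outside DD)."""
    out = np.zeros_like(t)
    run_start = None
    for ep in schedule.epochs:
        dark = ep.photoperiod == 0.0 or ep.intensity == 0.0
        if dark:
            if run_start is None:
                run_start = ep.start
            m = (t >= ep.start) & (t < ep.end)
            out[m] = (t[m] - run_start) / 24.0
        else:
            run_start = None
    return out


def _mouse_waveform(p: OscillatorParams, onsets: np.ndarray,
                    tm: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(onsets, tm, side="right") - 1
    active = (idx >= 0) & (tm < onsets[np.clip(idx, 0, None)] + p.alpha)
    return active.astype(float)


def _fly_waveform(p: OscillatorParams, onsets: np.ndarray,
                  tm: np.ndarray) -> np.ndarray:
    """Morning and evening raised-cosine bouts with anticipation ramps.

    The evening bout has full amplitude; the morning bout is scaled by
    ``morning_weight`` (fly activity is evening-dominant, which also keeps a
    circadian fundamental in the spectrum of the bimodal waveform).
    """
    w = np.zeros_like(tm)
    for events, amp in ((onsets, p.morning_weight),
                        (onsets + p.evening_offset, 1.0)):
        if amp <= 0:
            continue
        # nearest most-recent and upcoming event per bin
        for shift in (0, 1):
            j = np.searchsorted(events, tm) - 1 + shift
            ok = (j >= 0) & (j < events.size)
            c = events[np.clip(j, 0, events.size - 1)]
            d = tm - c
            bump = np.where(ok & (np.abs(d) <= p.bout_halfwidth),
                            0.5 * (1 + np.cos(np.pi * d / p.bout_halfwidth)), 0.0)
            # anticipation ramp anchored at the bout center so it merges
            # monotonically into the rising flank of the cosine bout
            ramp = np.where(ok & (d < 0.0) & (d > -6.0),
                            p.anticipation_amp * np.exp(d / p.anticipation_tau_h),
                            0.0)
            w = np.maximum(w, amp * np.maximum(bump, ramp))
    return np.minimum(w, 1.0)


def simulate_activity(config: BehaviorSimConfig, schedule: LightSchedule,
                      duration_hours: float | None = None,
                      return_truth: bool = False):
    """Simulate a cohort of activity traces under a light schedule.

    Returns a list of :class:`ActivityTrace` (and, with ``return_truth``,
    a parallel list of per-subject dicts holding each component's true onset
    times and tau trajectory).  Bit-reproducible given ``config.seed``.
    """
    span = schedule.span if duration_hours is None else duration_hours
    if span > schedule.span + 1e-9:
        raise ValueError("schedule shorter than the requested duration")
    bh = config.bin_minutes / 60.0
    n_bins = int(round(span / bh))
    tm = schedule.start + (np.arange(n_bins) + 0.5) * bh
    event = "lights_off" if config.species == "mouse" else "lights_on"
    refs = _reference_times(schedule, event)
    light_on = np.asarray(schedule.light_at(tm)) > 0
    dd_days = _dd_days(schedule, tm)
    weights = np.array([w for _, w in config.components])
    masking = float(sum(w * p.masking for p, w in config.components))
    rate_rest = float(sum(w * p.rate_rest for p, w in config.components))

    traces, truths = [], []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                           spawn_key=(i,)))
        rate = np.full(n_bins, rate_rest)
        truth = {"components": []}
        for (p, w) in config.components:
            onsets, taus = _component_onsets(p, refs, span, rng)
            wave = (_mouse_waveform(p, onsets, tm) if config.species == "mouse"
                    else _fly_waveform(p, onsets, tm))
            decay = p.amplitude_decay ** dd_days if p.amplitude_decay != 1.0 else 1.0
            rate = rate + w * p.rate_active * decay * wave
            inside = onsets < schedule.start + span  # trailing extras serve
            truth["components"].append({"onsets": onsets[inside],  # waveform only
                                        "taus": taus[:int(inside.sum())],
                                        "weight": w})
        rate = rate * (1.0 - masking * light_on)
        counts = rng.poisson(rate)
        traces.append(ActivityTrace(f"{config.species[0]}{i + 1:02d}",
                                    config.species, config.bin_minutes,
                                    schedule.start, counts))
        truths.append(truth)
    return (traces, truths) if return_truth else traces


# ---------------------------------------------------------------------------
# proteome generator
# ---------------------------------------------------------------------------

@dataclass
class ProteomeSimConfig:
    """Configuration of the synthetic LFQ protein table.

    The defaults emulate a deep HEK293T-scale LFQ experiment: ~4,000
    quantified proteins in two groups of four, log2 intensities centered at
    25 with between-protein SD 2 and within-group SD 0.3, 10% of proteins
    carrying a true |log2 fold-change| drawn around 1, and left-censored
    missingness (logistic in abundance) plus decoy/contaminant/site-only
    rows as a MaxQuant search would emit.
    """

    n_proteins: int = 4000
    n_per_group: tuple[int, int] = (4, 4)
    group_names: tuple[str, str] = ("WT", "KO")
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.3
    dep_fraction: float = 0.1
    effect_mean: float = 1.0
    effect_sd: float = 0.5
    missing_midpoint: float = 21.0
    missing_slope: float = 1.0
    n_decoy: int = 50
    n_contaminant: int = 30
    n_site_only: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_decoy, self.n_contaminant,
               self.n_site_only) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.dep_fraction <= 1.0:
            raise ValueError("dep_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def simulate_protein_table(config: ProteomeSimConfig):
    """Generate a raw-scale protein table plus its ground-truth effect table.

    Returns ``(table, truth)`` where ``table`` is a
    :class:`~rhythmlab.proteomics.ProteinTable` on the raw intensity scale
    (missing cells NaN) and ``truth`` a DataFrame with each real protein's
    true log2 effect (group 2 minus group 1) and a ``is_dep`` flag.
    """
    from .proteomics import ProteinTable  # deferred: avoid cycle at import

    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_per_group
    g1, g2 = config.group_names
    samples = [f"{g1}{i + 1}" for i in range(n1)] + [f"{g2}{i + 1}" for i in range(n2)]
    n = config.n_proteins

    base = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    is_dep = rng.random(n) < config.dep_fraction
    effect = np.where(
        is_dep,
        np.abs(rng.normal(config.effect_mean, config.effect_sd, size=n))
        * rng.choice([-1.0, 1.0], size=n),
        0.0,
    )
    y = (base[:, None]
         + np.outer(effect, np.r_[np.zeros(n1), np.ones(n2)])
         + rng.normal(0.0, config.noise_sd, size=(n, n1 + n2)))
    p_miss = 1.0 / (1.0 + np.exp((y - config.missing_midpoint) * config.missing_slope))
    missing = rng.random(y.shape) < p_miss
    raw = np.where(missing, np.nan, 2.0 ** y)

    ids = [f"P{i + 1:05d}" for i in range(n)]
    n_flag = config.n_decoy + config.n_contaminant + config.n_site_only
    flag_ids = [f"FLAG{i + 1:04d}" for i in range(n_flag)]
    flag_y = rng.normal(config.baseline_mean - 3.0, config.baseline_sd,
                        size=(n_flag, n1 + n2))
    flag_missing = rng.random(flag_y.shape) < 0.3
    flag_raw = np.where(flag_missing, np.nan, 2.0 ** flag_y)

    intens = pd.DataFrame(np.vstack([raw, flag_raw]) if n_flag else raw,
                          index=ids + flag_ids, columns=samples)
    flags = pd.DataFrame(False, index=intens.index,
                         columns=["only_identified_by_site", "reverse",
                                  "potential_contaminant"])
    r0 = n
    flags.iloc[r0:r0 + config.n_decoy, 1] = True
    r0 += config.n_decoy
    flags.iloc[r0:r0 + config.n_contaminant, 2] = True
    r0 += config.n_contaminant
    flags.iloc[r0:r0 + config.n_site_only, 0] = True

    truth = pd.DataFrame({"protein_id": ids, "log2_effect": effect,
                          "is_dep": is_dep}).set_index("protein_id")
    return ProteinTable(intens, flags, log2_scale=False), truth
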