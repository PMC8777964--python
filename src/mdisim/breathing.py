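"""Inhalation waveform, actuation step and their relative timing.

The delivery scenario couples two clocks: the patient's inhalation (a deep,
slow breath lasting 5 s with a peak flow of 61.2 L/min at 1.23 s, followed by
a 1 s breath-hold) and the device actuation (a 0.2 s step that may start at
any offset from inhalation onset).  The offset is the coordination variable
under study.

The printed waveform constraints fix only the peak value, peak time and
duration, so the profile shape is a documented closure: a quarter-sine rise
to the peak followed by a half-cosine decay to zero, which is continuous,
has a single interior maximum and matches the constraints exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "InhalationProfile",
    "ActuationSchedule",
    "ScenarioConfig",
    "flow_at",
    "mean_mouthpiece_speed",
    "actuation_active",
    "load_scenarios",
]

#: L/min -> m^3/s
LPM_TO_M3S = 1.0 / 60000.0


@dataclass(frozen=True)
class InhalationProfile:
    """Deep-slow inhalation waveform (flow in L/min, time in s)."""

    peak_flow_lpm: float = 61.2
    t_peak_s: float = 1.23
    inhale_duration_s: float = 5.0
    breath_hold_s: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_flow_lpm <= 0.0:
            raise ValueError("peak flow must be positive")
        if not (0.0 < self.t_peak_s < self.inhale_duration_s):
            raise ValueError("t_peak must lie strictly inside the inhalation")
        if self.breath_hold_s < 0.0:
            raise ValueError("breath hold must be non-negative")

    @property
    def total_time_s(self) -> float:
        """Total simulated delivery time (inhalation plus breath-hold)."""
        return self.inhale_duration_s + self.breath_hold_s

    def flow_at(self, t):
        """Volumetric inhalation flow (L/min) at time ``t`` (s from onset)."""
        return flow_at(self, t)

    def inhaled_volume_l(self, t_end: float | None = None) -> float:
        """Inhaled volume (L) from onset to ``t_end`` by numerical quadrature."""
        t_end = self.inhale_duration_s if t_end is None else min(t_end, self.total_time_s)
        vol_per_s, _ = quad(lambda t: flow_at(self, t) / 60.0, 0.0, t_end, limit=200)
        return vol_per_s

    def cumulative_volume_interpolator(self, dt: float = 1e-3):
        """Return ``(t_grid, v_grid)`` of cumulative inhaled volume in litres.

        A dense trapezoid grid over the full delivery time; cheap to invert
        with ``np.interp`` in either direction (volume is non-decreasing).
        """
        t = np.arange(0.0, self.total_time_s + dt, dt)
        q = flow_at(self, t) / 60.0  # L/s
        v = np.concatenate([[0.0], np.cumsum(0.5 * (q[1:] + q[:-1]) * np.diff(t))])
        return t, v


def flow_at(profile: InhalationProfile, t):
    """Evaluate the inhalation waveform (L/min); vectorized over ``t``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("time must be non-negative")
    qp, tp, T = profile.peak_flow_lpm, profile.t_peak_s, profile.inhale_duration_s
    rise = qp * np.sin(0.5 * math.pi * t_arr / tp)
    decay = 0.5 * qp * (1.0 + np.cos(math.pi * (t_arr - tp) / (T - tp)))
    q = np.where(t_arr <= tp, rise, decay)
    q = np.where(t_arr >= T, 0.0, q)
    return float(q) if np.isscalar(t) else q


def mean_mouthpiece_speed(q_lpm: float, area_cm2: float = 1.28) -> float:
    """Average flow speed (m/s) through a cross-section of the given area."""
    if area_cm2 <= 0.0:
        raise ValueError("area must be positive")
    if q_lpm < 0.0:
        raise ValueError("flow must be non-negative")
    return q_lpm * LPM_TO_M3S / (area_cm2 * 1e-4)


@dataclass(frozen=True)
class ActuationSchedule:
    """Device actuation step: onset offset from inhalation onset plus duration."""

    t_act_s: float = 0.63
    duration_s: float = 0.2

    def __post_init__(self) -> None:
        if self.t_act_s < 0.0:
            raise ValueError("actuation offset must be non-negative")
        if self.duration_s <= 0.0:
            raise ValueError("actuation duration must be positive")

    def active(self, t):
        return actuation_active(self, t)


def actuation_active(schedule: ActuationSchedule, t):
    """True iff ``t`` falls in the half-open actuation window [t_act, t_act+dur)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("time must be non-negative")
    # Half-open window; the closing edge is detected with a tolerance so that
    # t_act + duration round-off (e.g. 0.63 + 0.2 vs 0.83) stays outside.
    delta = t_arr - schedule.t_act_s
    at_edge = np.isclose(delta, schedule.duration_s, rtol=1e-12, atol=1e-12)
    out = (delta >= 0.0) & (delta < schedule.duration_s) & ~at_edge
    return bool(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class ScenarioConfig:
    """One delivery case: waveform, actuation timing, label and seed."""

    profile: InhalationProfile = field(default_factory=InhalationProfile)
    schedule: ActuationSchedule = field(default_factory=ActuationSchedule)
    label: str = "control"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        end = self.schedule.t_act_s + self.schedule.duration_s
        if end > self.profile.total_time_s:
            raise ValueError(
                f"actuation window ends at {end:.3f} s, beyond the simulated "
                f"delivery time of {self.profile.total_time_s:.3f} s"
            )


def load_scenarios(path) -> list[ScenarioConfig]:
    """Load a scenario comparison set from a YAML file.

    Layout::

        profile: {peak_flow_lpm: 61.2, t_peak_s: 1.23, ...}   # optional
        duration_s: 0.2                                       # optional
        seed: 0                                               # optional
        scenarios:
          - {label: control, t_act: 0.63}
          - {label: early, t_act: 0.0}

    Labels must be unique within the set.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    profile = InhalationProfile(**raw.get("profile", {}))
    duration = float(raw.get("duration_s", 0.2))
    seed = int(raw.get("seed", 0))
    entries = raw.get("scenarios", [])
    if not entries:
        raise ValueError(f"no scenarios defined in {path}")
    labels = [e.get("label", f"t_act={e['t_act']:g}") for e in entries]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique within a comparison set")
    return [
        ScenarioConfig(
            profile=profile,
            schedule=ActuationSchedule(t_act_s=float(e["t_act"]), duration_s=duration),
            label=label,
            rng_seed=int(e.get("seed", seed)),
        )
        for e, label in zip(entries, labels)
    ]
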