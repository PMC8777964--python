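"""Reduced-order Lagrangian march of droplets through the delivery phases.

Each droplet passes through three phases, mirroring the observed spray
evolution (discharging from the orifice, dispersion in the oral cavity,
dispensing to the lung):

Phase 1 -- discharging (first ~10 ms after a droplet's release).  The spray
jet throws the cloud across the mouthpiece and mouth.  Droplets whose lateral
ballistic reach exceeds the duct radius deposit on the mouthpiece/mouth wall.
The survivors face an inertial-impaction draw at the back-throat bend, with a
Stokes number built from the droplet diameter and a characteristic arrival
speed: the decayed (confined) jet remnant plus the instantaneous bulk
inhalation speed at release.  The background-speed term is the mechanism by
which actuation timing changes oropharyngeal dose.  If the background flow at
release is quiescent (actuation before inhalation has ramped up), surviving
droplets are instead held near the device and settle there until the flow
picks up.

Phase 2 -- dispersion.  Surviving droplets join a well-mixed mouth reservoir
(the dispersion phase homogenizes the cloud): uniform depth along the mouth,
uniform height above the floor.  Clearance is plug-flow ordered by depth: a
droplet leaves when the cumulative inhaled volume since its suspension
exceeds an entrainment multiple of its downstream mouth volume
(recirculation makes the effective washout volume several cavity volumes).
Gravitational settling races the clearance.  If the inhalation ends before
the required volume is drawn, the droplet is trapped and settles through the
remaining delivery time, or stays airborne.

Phase 3 -- dispensing.  Cleared droplets traverse pharynx -> larynx ->
trachea (G0) ... terminal generation, with per-segment deposition
probabilities: inertial impaction at the instantaneous segment mean velocity
and gravitational sedimentation over the residence time.  Bernoulli draws use
one dedicated random row per droplet id, so results are independent of
iteration order.  Droplets passing the terminal generation are recorded as
exited through their outlet; lobar routing follows the flow split rule
(default: proportional to downstream outlet count).  Droplets stranded
without flow (breath-hold) deposit if terminal-velocity settling covers the
local radius within the remaining time, else remain airborne.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .aerosol import AirProperties, DropletPopulation
from .airway import AirwayTree, Region
from .breathing import LPM_TO_M3S, ScenarioConfig, flow_at
from .jet import relaxation_time, schiller_naumann, terminal_velocity

__all__ = [
    "TransportConfig",
    "DropletFate",
    "MouthReservoirState",
    "RECORD_COLUMNS",
    "impaction_probability",
    "sedimentation_probability",
    "back_throat_stokes",
    "simulate_scenario",
    "records_to_fates",
    "count_sensitivity",
]

RECORD_COLUMNS = [
    "droplet_id",
    "diameter_um",
    "mass_kg",
    "status",
    "region",
    "generation",
    "lobe",
    "outlet_id",
    "fate_time_s",
    "patch_id",
]

STATUS_DEPOSITED = "deposited"
STATUS_EXITED = "exited"
STATUS_AIRBORNE = "airborne"


@dataclass(frozen=True)
class TransportConfig:
    """Closure parameters of the reduced-order transport model."""

    dt: float = 5e-4  # grid resolution for waveform/volume bookkeeping
    dispersion: bool = False  # turbulent random-walk addition to settling
    eddy_intensity: float = 5e-4  # m^2/s, used when dispersion is on
    lobar_fractions: dict | None = None  # None -> split by downstream outlet count
    breath_hold_settling: bool = True
    clearance_factor: float = 40.0  # cavity volumes drawn to clear the reservoir
    quiescent_speed: float = 0.7  # m/s mouth mean speed below which flow is quiescent
    jet_decay_constant: float = 6.0  # confined in-airway jet decay constant
    orifice_diameter_mm: float = 0.5
    impaction_coeff: float = 1.2
    bt_char_diameter_m: float = 0.008  # back-throat bend characteristic diameter
    bt_bend_angle_deg: float = 90.0
    min_speed: float = 1e-3  # m/s, below this a segment is treated as flow-free
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if self.clearance_factor <= 0.0:
            raise ValueError("clearance factor must be positive")
        if self.lobar_fractions is not None:
            bad = [k for k in self.lobar_fractions if k not in ("LU", "LL", "RU", "RM", "RL")]
            if bad:
                raise ValueError(f"unknown lobes in lobar_fractions: {bad}")


@dataclass(frozen=True)
class DropletFate:
    """Final fate of one droplet."""

    droplet_id: int
    status: str  # deposited | exited | airborne
    region: str | None
    generation: int | None
    lobe: str | None
    outlet_id: int | None
    fate_time_s: float
    patch_id: str


@dataclass
class MouthReservoirState:
    """Snapshot of the suspended mouth inventory after the dispersion phase."""

    droplet_ids: np.ndarray
    depth_fraction: np.ndarray  # position along the mouth, 0 (front) .. 1 (back)
    height_m: np.ndarray  # above the cavity floor
    suspension_time_s: np.ndarray


def impaction_probability(stk, branch_angle_deg, coeff: float = 2.0):
    """Inertial impaction probability for a bend/bifurcation.

    ``p = 1 - exp(-coeff * Stk * (0.05 + sin(angle)))``: zero at Stk = 0,
    monotone non-decreasing in both arguments, saturating at 1.  The 0.05
    floor keeps a weak Stk dependence for straight segments (carinal ridges,
    wall curvature).
    """
    stk_arr = np.asarray(stk, dtype=float)
    if np.any(stk_arr < 0.0):
        raise ValueError("Stokes number must be non-negative")
    ang = np.radians(np.asarray(branch_angle_deg, dtype=float))
    p = 1.0 - np.exp(-coeff * stk_arr * (0.05 + np.sin(ang)))
    return float(p) if (np.isscalar(stk) and np.isscalar(branch_angle_deg)) else p


def sedimentation_probability(terminal_speed, residence_time, tube_diameter, gravity_angle_deg):
    """Gravitational settling probability in an inclined tube.

    The settling distance across the lumen is ``v_t * t * sin(gamma)`` with
    ``gamma`` the angle between the tube axis and gravity; the probability is
    that distance over the tube diameter, capped at 1.  A horizontal tube
    (gamma = 90 deg) with settling distance >= diameter deposits certainly; a
    vertical tube has no cross-stream settling.
    """
    vt = np.asarray(terminal_speed, dtype=float)
    t = np.asarray(residence_time, dtype=float)
    d = np.asarray(tube_diameter, dtype=float)
    if np.any(vt < 0.0) or np.any(t < 0.0) or np.any(d < 0.0):
        raise ValueError("all sedimentation inputs must be non-negative")
    gamma = np.radians(np.asarray(gravity_angle_deg, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.clip(vt * t * np.abs(np.sin(gamma)) / np.where(d > 0, d, np.inf), 0.0, 1.0)
    scalar = all(
        np.isscalar(v) for v in (terminal_speed, residence_time, tube_diameter, gravity_angle_deg)
    )
    return float(p) if scalar else p


def back_throat_stokes(diameter_um, char_speed, density: float = 1000.0,
                       char_diameter_m: float = 0.015,
                       air: AirProperties = AirProperties()):
    """Stokes number of the back-throat bend at the given arrival speed."""
    d_m = np.asarray(diameter_um, dtype=float) * 1e-6
    stk = density * d_m**2 * np.asarray(char_speed, dtype=float) / (
        18.0 * air.viscosity * char_diameter_m
    )
    return float(stk) if np.isscalar(diameter_um) and np.isscalar(char_speed) else stk


def _segment_arrays(tree: AirwayTree):
    """Dense per-id lookup arrays plus child index tables."""
    n_ids = max(tree.segments) + 1
    length = np.zeros(n_ids)
    diameter = np.zeros(n_ids)
    branch = np.zeros(n_ids)
    gravity = np.zeros(n_ids)
    for seg in tree.segments.values():
        length[seg.id] = seg.length_m
        diameter[seg.id] = seg.diameter_m
        branch[seg.id] = seg.branch_angle_deg
        gravity[seg.id] = seg.gravity_angle_deg
    child0 = np.full(n_ids, -1, dtype=int)
    child1 = np.full(n_ids, -1, dtype=int)
    for parent, kids in tree.children.items():
        if len(kids) == 2:
            child0[parent], child1[parent] = kids
    return length, diameter, branch, gravity, child0, child1


def _subtree_probabilities(tree: AirwayTree, config: TransportConfig, split_level: int):
    """Routing probability of each split-level subtree."""
    n_sub = 2**split_level
    if config.lobar_fractions is None or split_level < 3:
        # Symmetric tree: downstream outlet counts are equal per subtree.
        return np.full(n_sub, 1.0 / n_sub)
    rule = tree.config.lobe_rule
    counts = {lb: rule.count(lb) for lb in set(rule)}
    p = np.array(
        [config.lobar_fractions.get(lb, 0.0) / counts[lb] for lb in rule], dtype=float
    )
    total = p.sum()
    if total <= 0.0:
        raise ValueError("lobar fractions sum to zero")
    return p / total


class _FateWriter:
    """Accumulates per-droplet fates into flat arrays."""

    def __init__(self, n: int, t_total: float):
        self.n = n
        self.t_total = t_total
        self.status = np.full(n, "", dtype=object)
        self.region = np.full(n, "", dtype=object)
        self.generation = np.full(n, -1, dtype=int)
        self.lobe = np.full(n, "", dtype=object)
        self.outlet = np.full(n, -1, dtype=int)
        self.fate_time = np.full(n, t_total, dtype=float)
        self.patch = np.full(n, "", dtype=object)

    def deposit(self, ids, region, seg_ids, frac, times, gen=-1, lobes=None):
        ids = np.atleast_1d(ids)
        if ids.size == 0:
            return
        self.status[ids] = STATUS_DEPOSITED
        self.region[ids] = region
        self.generation[ids] = gen
        if lobes is not None:
            self.lobe[ids] = lobes
        self.fate_time[ids] = np.minimum(np.atleast_1d(times), self.t_total)
        seg_ids = np.broadcast_to(np.atleast_1d(seg_ids), ids.shape)
        bins = np.clip((np.broadcast_to(np.atleast_1d(frac), ids.shape) * 10).astype(int), 0, 9)
        self.patch[ids] = [f"{region}:{s}:{b}" for s, b in zip(seg_ids, bins)]

    def airborne(self, ids):
        ids = np.atleast_1d(ids)
        if ids.size:
            self.status[ids] = STATUS_AIRBORNE

    def exit(self, ids, outlets, lobes, times):
        ids = np.atleast_1d(ids)
        if ids.size == 0:
            return
        self.status[ids] = STATUS_EXITED
        self.outlet[ids] = outlets
        self.lobe[ids] = lobes
        self.fate_time[ids] = np.minimum(times, self.t_total)


def simulate_scenario(
    population: DropletPopulation,
    tree: AirwayTree,
    scenario: ScenarioConfig,
    config: TransportConfig | None = None,
    air: AirProperties = AirProperties(),
) -> pd.DataFrame:
    """Run one delivery case and return the per-droplet deposition records.

    Returns a table with :data:`RECORD_COLUMNS` and exactly one row per
    droplet; every droplet ends deposited (in a region), exited (through a
    terminal outlet) or airborne.  Use :func:`records_to_fates` for a
    dataclass view.  The reservoir snapshot is attached as
    ``records.attrs["reservoir"]``.
    """
    cfg = config if config is not None else TransportConfig()
    n = len(population)
    if n == 0:
        return pd.DataFrame(columns=RECORD_COLUMNS)

    profile = scenario.profile
    t_total = profile.total_time_s
    seed = cfg.rng_seed if cfg.rng_seed is not None else scenario.rng_seed
    rng = np.random.default_rng(seed)

    depth = tree.config.tree_depth
    split_level = min(3, depth)
    n_stage = 2 + depth + 1  # pharynx, larynx, G0..Gdepth

    # One random row per droplet id, draws indexed by purpose: outcomes are
    # independent of evaluation order.
    u_bt = rng.random(n)
    u_depth = rng.random(n)
    u_height = rng.random(n)
    u_subtree = rng.random(n)
    u_leaf = rng.random(n)
    stage_draws = rng.random((n, n_stage))
    xi_disp = np.abs(rng.standard_normal(n))

    d_um = population.diameters_um
    rho_p = population.density
    v_t = terminal_velocity(d_um, rho_p, air)
    t_rel = scenario.schedule.t_act_s + population.release_times_s

    ext = tree.extrathoracic_ids()
    seg_mp = tree.segments[ext[0]]
    seg_mouth = tree.segments[ext[1]]
    seg_phar = tree.segments[ext[2]]
    seg_lar = tree.segments[ext[3]]
    trachea = tree.trachea_id()
    seg_len, seg_diam, seg_branch, seg_gravity, child0, child1 = _segment_arrays(tree)

    a_mouth = seg_mouth.area_m2
    d_mouth = seg_mouth.diameter_m
    l_mouth = seg_mouth.length_m
    l_path = seg_mp.length_m + l_mouth

    # Waveform bookkeeping: flow and cumulative inhaled volume on a dense grid.
    t_grid = np.arange(0.0, t_total + cfg.dt, cfg.dt)
    q_lps = flow_at(profile, t_grid) / 60.0  # L/s
    v_grid = np.concatenate([[0.0], np.cumsum(0.5 * (q_lps[1:] + q_lps[:-1]) * np.diff(t_grid))])
    v_end = float(v_grid[-1])

    q_rel_lpm = flow_at(profile, t_rel)
    u_bg = q_rel_lpm * LPM_TO_M3S / a_mouth  # bulk mouth speed at each release

    out = _FateWriter(n, t_total)

    # ------------------------------------------------------------------
    # Phase 1: discharging.
    # ------------------------------------------------------------------
    u0 = population.speeds
    sin_phi = np.sqrt(np.maximum(1.0 - population.directions[:, 0] ** 2, 0.0))
    v_lat0 = u0 * sin_phi
    rel_re = air.density * u0 * d_um * 1e-6 / air.viscosity
    tau_eff = relaxation_time(d_um, rho_p, air) / schiller_naumann(rel_re)

    # Lateral ballistic reach vs. duct radius (plume-cone spread check).
    r_reach = v_lat0 * tau_eff
    s_lat = np.where(sin_phi > 1e-12, 1.0, np.inf) * (1.0 / np.maximum(sin_phi, 1e-12))
    s_hit_mp = (seg_mp.diameter_m / 2.0) * s_lat
    s_hit_mouth = (d_mouth / 2.0) * s_lat
    hit_mp = (r_reach >= seg_mp.diameter_m / 2.0) & (s_hit_mp <= seg_mp.length_m)
    hit_mouth = ~hit_mp & (r_reach >= d_mouth / 2.0) & (s_hit_mouth <= l_path)
    out.deposit(
        np.flatnonzero(hit_mp), Region.MDI_MOUTHPIECE, seg_mp.id,
        np.clip(s_hit_mp[hit_mp] / seg_mp.length_m, 0.0, 0.999), t_rel[hit_mp] + 2e-3,
    )
    out.deposit(
        np.flatnonzero(hit_mouth), Region.MOUTH, seg_mouth.id,
        np.clip((s_hit_mouth[hit_mouth] - seg_mp.length_m) / l_mouth, 0.0, 0.999),
        t_rel[hit_mouth] + 2e-3,
    )
    flying = ~(hit_mp | hit_mouth)

    # Back-throat bend impaction: confined-jet remnant speed at the end of
    # the mouth path plus the instantaneous inhalation speed at release.
    jet_remnant = cfg.jet_decay_constant * u0 * (cfg.orifice_diameter_mm * 1e-3) / l_path
    u_char = jet_remnant + u_bg
    stk_bt = back_throat_stokes(d_um, u_char, rho_p, cfg.bt_char_diameter_m, air)
    p_bt = impaction_probability(stk_bt, cfg.bt_bend_angle_deg, cfg.impaction_coeff)
    bt = flying & (u_bt < p_bt)
    out.deposit(
        np.flatnonzero(bt), Region.MOUTH, seg_mouth.id, 0.95,
        t_rel[bt] + l_path / np.maximum(0.5 * (u0[bt] + u_char[bt]), 1.0),
    )
    flying &= ~bt

    # Quiescent hold: firing into an airway without appreciable inhalation
    # flow leaves the cloud near the device, where it settles until the flow
    # exceeds the quiescent threshold.
    u_grid = flow_at(profile, t_grid) * LPM_TO_M3S / a_mouth
    above = u_grid >= cfg.quiescent_speed
    t_entrain = float(t_grid[np.argmax(above)]) if above.any() else math.inf
    quiescent = flying & (u_bg < cfg.quiescent_speed)
    if quiescent.any():
        q_ids = np.flatnonzero(quiescent)
        h_dev = u_height[q_ids] * seg_mp.diameter_m
        t_settle = h_dev / np.maximum(v_t[q_ids], 1e-300)
        t_avail = min(t_entrain, t_total) - t_rel[q_ids]
        dep = t_settle <= t_avail
        out.deposit(
            q_ids[dep], Region.MDI_MOUTHPIECE, seg_mp.id, u_depth[q_ids[dep]],
            t_rel[q_ids[dep]] + t_settle[dep],
        )
        flying[q_ids[dep]] = False
        if math.isinf(t_entrain):
            # Flow never starts: survivors stay airborne near the device.
            out.airborne(np.flatnonzero(flying & quiescent))
            flying &= ~quiescent

    # ------------------------------------------------------------------
    # Phase 2: dispersion / mouth reservoir.
    # ------------------------------------------------------------------
    ids_r = np.flatnonzero(flying)
    t_susp = t_rel[ids_r].copy()
    if not math.isinf(t_entrain):
        held = u_bg[ids_r] < cfg.quiescent_speed
        t_susp[held] = np.maximum(t_susp[held], t_entrain)
    depth_frac = u_depth[ids_r]
    height = u_height[ids_r] * d_mouth
    reservoir = MouthReservoirState(
        droplet_ids=ids_r.copy(),
        depth_fraction=depth_frac.copy(),
        height_m=height.copy(),
        suspension_time_s=t_susp.copy(),
    )

    v_req = cfg.clearance_factor * a_mouth * l_mouth * (1.0 - depth_frac) * 1e3  # litres
    v_start = np.interp(t_susp, t_grid, v_grid)
    t_clear = np.interp(v_start + v_req, v_grid, t_grid, right=np.inf)
    trapped = (v_start + v_req > v_end - 1e-12) | ~np.isfinite(t_clear)

    window = np.where(trapped, t_total - t_susp, t_clear - t_susp)
    settle_dist = v_t[ids_r] * window
    if cfg.dispersion:
        # Half-normal random-walk excursion toward the floor, added to the
        # deterministic settling displacement.
        settle_dist = settle_dist + xi_disp[ids_r] * np.sqrt(
            2.0 * cfg.eddy_intensity * np.maximum(window, 0.0)
        )
    settles = settle_dist >= height
    t_dep = t_susp + height / np.maximum(v_t[ids_r], 1e-300)
    out.deposit(
        ids_r[settles], Region.MOUTH, seg_mouth.id, depth_frac[settles],
        np.minimum(t_dep[settles], t_total),
    )
    out.airborne(ids_r[trapped & ~settles])

    go = ~trapped & ~settles
    ids = ids_r[go]
    t_in = t_clear[go]

    # ------------------------------------------------------------------
    # Phase 3: dispensing through pharynx, larynx and the TB tree.
    # ------------------------------------------------------------------
    sub_p = _subtree_probabilities(tree, cfg, split_level)
    sub_idx = np.clip(
        np.searchsorted(np.cumsum(sub_p), u_subtree, side="right"), 0, len(sub_p) - 1
    )
    n_leaf = 2 ** max(depth - split_level, 0)
    leaf_idx = np.minimum((u_leaf * n_leaf).astype(int), n_leaf - 1)
    if split_level == 3:
        lobe_of_subtree = np.array(tree.config.lobe_rule, dtype=object)
        path_lobe = lobe_of_subtree[sub_idx]
    else:
        path_lobe = np.full(n, "", dtype=object)

    def stage_transit(ids, t_in, seg_ids, region_label, gen, stage_i, with_lobe):
        """One-segment transit; returns (surviving mask, exit times)."""
        survived = np.zeros(ids.size, dtype=bool)
        t_out = np.zeros(ids.size)
        if ids.size == 0:
            return survived, t_out
        length = seg_len[seg_ids]
        diam = seg_diam[seg_ids]
        area = math.pi * diam**2 / 4.0
        branch_count = 2**gen if gen >= 0 else 1
        q_now = flow_at(profile, np.minimum(t_in, t_total)) * LPM_TO_M3S
        u_seg = q_now / (area * branch_count)

        lobes = path_lobe[ids] if with_lobe else None

        stuck = u_seg < cfg.min_speed
        if stuck.any():
            hold = t_total - t_in[stuck]
            can_settle = cfg.breath_hold_settling & (v_t[ids[stuck]] * hold >= diam[stuck] / 2.0)
            dep_sel = np.flatnonzero(stuck)[can_settle]
            out.deposit(
                ids[dep_sel], region_label, seg_ids[dep_sel], 0.5,
                t_in[dep_sel] + (diam[dep_sel] / 2.0) / np.maximum(v_t[ids[dep_sel]], 1e-300),
                gen=gen, lobes=lobes[dep_sel] if with_lobe else None,
            )
            out.airborne(ids[np.flatnonzero(stuck)[~can_settle]])

        moving = np.flatnonzero(~stuck)
        if moving.size == 0:
            return survived, t_out
        u_m = u_seg[moving]
        t_res = length[moving] / u_m
        stk = rho_p * (d_um[ids[moving]] * 1e-6) ** 2 * u_m / (18.0 * air.viscosity * diam[moving])
        p_imp = impaction_probability(stk, seg_branch[seg_ids[moving]], cfg.impaction_coeff)
        p_sed = sedimentation_probability(
            v_t[ids[moving]], t_res, diam[moving], seg_gravity[seg_ids[moving]]
        )
        p_dep = 1.0 - (1.0 - p_imp) * (1.0 - p_sed)
        dep = stage_draws[ids[moving], stage_i] < p_dep
        dep_sel = moving[dep]
        out.deposit(
            ids[dep_sel], region_label, seg_ids[dep_sel], 0.5,
            t_in[dep_sel] + 0.5 * t_res[dep],
            gen=gen, lobes=lobes[dep_sel] if with_lobe else None,
        )
        keep = moving[~dep]
        survived[keep] = True
        t_out[keep] = t_in[keep] + t_res[~dep]
        return survived, t_out

    def run_stage(ids, t_in, cur_seg, seg_ids, region_label, gen, stage_i, with_lobe):
        mask, t_out = stage_transit(ids, t_in, seg_ids, region_label, gen, stage_i, with_lobe)
        return ids[mask], t_out[mask], (cur_seg[mask] if cur_seg is not None else None)

    ids, t_in, _ = run_stage(
        ids, t_in, None, np.full(ids.size, seg_phar.id), Region.PHARYNX, -1, 0, False
    )
    ids, t_in, _ = run_stage(
        ids, t_in, None, np.full(ids.size, seg_lar.id), Region.LARYNX, -1, 1, False
    )

    cur_seg = np.full(ids.size, trachea, dtype=int)
    for g in range(0, depth + 1):
        if ids.size == 0:
            break
        if g > 0:
            if g <= split_level:
                bit = (sub_idx[ids] >> (split_level - g)) & 1
            else:
                bit = (leaf_idx[ids] >> (depth - g)) & 1
            cur_seg = np.where(bit == 0, child0[cur_seg], child1[cur_seg])
        ids, t_in, cur_seg = run_stage(
            ids, t_in, cur_seg, cur_seg, Region.TB, g, 2 + g, g >= 3
        )

    out.exit(ids, cur_seg if ids.size else np.empty(0, dtype=int), path_lobe[ids], t_in)

    assert not (out.status == "").any(), "unassigned droplet fates"

    records = pd.DataFrame(
        {
            "droplet_id": population.ids,
            "diameter_um": d_um,
            "mass_kg": population.masses_kg,
            "status": out.status,
            "region": out.region,
            "generation": out.generation,
            "lobe": out.lobe,
            "outlet_id": out.outlet,
            "fate_time_s": out.fate_time,
            "patch_id": out.patch,
        }
    )[RECORD_COLUMNS]
    records.attrs["reservoir"] = reservoir
    records.attrs["scenario_label"] = scenario.label
    return records


def records_to_fates(records: pd.DataFrame) -> list[DropletFate]:
    """Dataclass view of a deposition-record table."""
    return [
        DropletFate(
            droplet_id=int(r.droplet_id),
            status=r.status,
            region=r.region or None,
            generation=None if r.generation < 0 else int(r.generation),
            lobe=r.lobe or None,
            outlet_id=None if r.outlet_id < 0 else int(r.outlet_id),
            fate_time_s=float(r.fate_time_s),
            patch_id=r.patch_id,
        )
        for r in records.itertuples()
    ]


def count_sensitivity(
    tree: AirwayTree,
    scenario: ScenarioConfig,
    counts=(20_000, 30_000, 45_000, 60_000, 75_000, 100_000, 150_000),
    repeats: int = 1,
    base_seed: int = 0,
    source_config=None,
    size_spec=None,
    transport_config: TransportConfig | None = None,
) -> pd.DataFrame:
    """Seed-droplet-count convergence table of regional deposition fractions.

    Runs the scenario at each droplet count (``repeats`` independent seeds
    per count) and tabulates the mass-based DF per region, plus the spread
    across repeats.
    """
    from .aerosol import SourceConfig, make_population
    from .dosimetry import deposition_fraction

    if not counts:
        raise ValueError("counts must be non-empty")
    src = source_config if source_config is not None else SourceConfig()
    regions = ["MDI_MOUTHPIECE", "MOUTH", "PHARYNX", "LARYNX", "TB"]
    rows = []
    for count in counts:
        for rep in range(repeats):
            seed = base_seed + 7919 * rep + int(count)
            pop = make_population(replace(src, n_droplets=int(count), rng_seed=seed), size_spec)
            sc = ScenarioConfig(
                profile=scenario.profile,
                schedule=scenario.schedule,
                label=f"{scenario.label}-n{count}-r{rep}",
                rng_seed=seed,
            )
            rec = simulate_scenario(pop, tree, sc, transport_config)
            for reg in regions:
                rows.append(
                    {
                        "count": int(count),
                        "repeat": rep,
                        "seed": seed,
                        "region": reg,
                        "df": deposition_fraction(rec, reg),
                    }
                )
    table = pd.DataFrame(rows)
    spread = (
        table.groupby(["count", "region"])["df"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "df_mean", "std": "df_std"})
    )
    return table.merge(spread, on=["count", "region"])
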