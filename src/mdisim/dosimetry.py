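"""Dosimetry statistics computed from deposition-record tables.

All metrics are mass-based: the deposition fraction (DF) of a region is the
summed droplet mass deposited there divided by the total mass of all seed
droplets (so exited and airborne mass appear as the residual, and the DF is
invariant to a uniform density rescale).  The deposition enhancement factor
(DEF) of a surface patch is the ratio of its local deposition density
(mass per area) to the airway-average density, which makes the area-weighted
mean DEF exactly 1.  Lobar penetration rates are the mass fractions exiting
terminal outlets of each lobe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transport import RECORD_COLUMNS, STATUS_DEPOSITED, STATUS_EXITED

__all__ = [
    "SurfacePatch",
    "DosimetryReport",
    "ScenarioComparison",
    "DEFAULT_PATCH_AREA_MM2",
    "deposition_fraction",
    "aggregate_df",
    "def_map",
    "penetration_rate",
    "build_report",
    "compare_scenarios",
    "make_fixture",
]

REGIONS = ("MDI_MOUTHPIECE", "MOUTH", "PHARYNX", "LARYNX", "TB")
LOBES = ("LU", "LL", "RU", "RM", "RL")

#: Area of a 0.5 mm-diameter sampling circle, the default DEF patch size.
DEFAULT_PATCH_AREA_MM2 = math.pi * 0.25**2


@dataclass(frozen=True)
class SurfacePatch:
    """A small airway-surface sampling area for local dose mapping."""

    patch_id: str
    region: str
    area_mm2: float = DEFAULT_PATCH_AREA_MM2

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0.0:
            raise ValueError("patch area must be positive")


@dataclass
class DosimetryReport:
    """Regional and lobar dosimetry of one scenario."""

    label: str
    regional_df: dict[str, float]
    lobar_df: dict[str, float]
    penetration: dict[str, float]
    exited_fraction: float
    airborne_fraction: float

    def metric_dict(self) -> dict[str, float]:
        out = {f"DF_{k}": v for k, v in self.regional_df.items()}
        out.update({f"DF_lobe_{k}": v for k, v in self.lobar_df.items()})
        out.update({f"penetration_{k}": v for k, v in self.penetration.items()})
        out["exited"] = self.exited_fraction
        out["airborne"] = self.airborne_fraction
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": k, "value": v} for k, v in self.metric_dict().items()]
        return pd.DataFrame(rows)


@dataclass
class ScenarioComparison:
    """Per-metric change from a baseline report to a variant report."""

    baseline_label: str
    variant_label: str
    table: pd.DataFrame  # metric, baseline, variant, absolute_change, percent_change

    def percent_change(self, metric: str) -> float:
        row = self.table.loc[self.table["metric"] == metric]
        if row.empty:
            raise KeyError(f"unknown metric {metric!r}")
        return float(row["percent_change"].iloc[0])

    def absolute_change(self, metric: str) -> float:
        row = self.table.loc[self.table["metric"] == metric]
        if row.empty:
            raise KeyError(f"unknown metric {metric!r}")
        return float(row["absolute_change"].iloc[0])


def _check_records(records: pd.DataFrame) -> None:
    if records is None or len(records) == 0:
        raise ValueError("empty deposition-record table")
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")


def deposition_fraction(records: pd.DataFrame, region: str) -> float:
    """Mass-based DF of one region: deposited mass there over total seed mass."""
    _check_records(records)
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}")
    total = records["mass_kg"].sum()
    dep = records.loc[
        (records["status"] == STATUS_DEPOSITED) & (records["region"] == region), "mass_kg"
    ].sum()
    return float(dep / total)


def aggregate_df(records: pd.DataFrame, regions) -> float:
    """Sum of member-region DFs (additive, order-independent)."""
    _check_records(records)
    regions = list(regions)
    unknown = [r for r in regions if r not in REGIONS]
    if unknown:
        raise KeyError(f"unknown region labels: {unknown}")
    return float(sum(deposition_fraction(records, r) for r in set(regions)))


def def_map(records: pd.DataFrame, patches: list[SurfacePatch], total_area_mm2: float) -> pd.DataFrame:
    """Deposition enhancement factor per surface patch.

    ``DEF_i = (patch mass / patch area) / (total deposited mass / total
    area)``; the area-weighted mean DEF over a complete patch set is 1 by
    construction.  Raises when nothing is deposited (DEF undefined).
    """
    _check_records(records)
    if total_area_mm2 <= 0.0:
        raise ValueError("total area must be positive")
    dep = records.loc[records["status"] == STATUS_DEPOSITED]
    total_mass = dep["mass_kg"].sum()
    if total_mass <= 0.0:
        raise ValueError("no deposited mass: DEF undefined")
    mean_density = total_mass / total_area_mm2
    by_patch = dep.groupby("patch_id")["mass_kg"].sum()
    rows = []
    for patch in patches:
        mass = float(by_patch.get(patch.patch_id, 0.0))
        rows.append(
            {
                "patch_id": patch.patch_id,
                "region": patch.region,
                "area_mm2": patch.area_mm2,
                "mass_kg": mass,
                "def": (mass / patch.area_mm2) / mean_density,
            }
        )
    return pd.DataFrame(rows)


def penetration_rate(records: pd.DataFrame, lobe: str) -> float:
    """Mass fraction exiting terminal outlets of one lobe (deep-lung dose)."""
    _check_records(records)
    if lobe not in LOBES:
        raise KeyError(f"unknown lobe {lobe!r}")
    total = records["mass_kg"].sum()
    mass = records.loc[
        (records["status"] == STATUS_EXITED) & (records["lobe"] == lobe), "mass_kg"
    ].sum()
    return float(mass / total)


def build_report(records: pd.DataFrame, label: str = "") -> DosimetryReport:
    """Full dosimetry summary of one scenario's record table."""
    _check_records(records)
    total = records["mass_kg"].sum()
    dep = records.loc[records["status"] == STATUS_DEPOSITED]
    regional = {r: deposition_fraction(records, r) for r in REGIONS}
    lobar = {
        lb: float(dep.loc[dep["lobe"] == lb, "mass_kg"].sum() / total) for lb in LOBES
    }
    penet = {lb: penetration_rate(records, lb) for lb in LOBES}
    exited = float(records.loc[records["status"] == STATUS_EXITED, "mass_kg"].sum() / total)
    airborne = float(records.loc[records["status"] == "airborne", "mass_kg"].sum() / total)
    if not label:
        label = records.attrs.get("scenario_label", "")
    return DosimetryReport(
        label=label,
        regional_df=regional,
        lobar_df=lobar,
        penetration=penet,
        exited_fraction=exited,
        airborne_fraction=airborne,
    )


def compare_scenarios(baseline: DosimetryReport, variant: DosimetryReport) -> ScenarioComparison:
    """Per-metric absolute and percent change from baseline to variant.

    Percent change is ``100 * (variant - baseline) / baseline``; for a zero
    baseline it is reported as NaN (undefined) while the absolute change is
    still reported.
    """
    base = baseline.metric_dict()
    var = variant.metric_dict()
    if set(base) != set(var):
        raise ValueError("reports carry different metric sets")
    rows = []
    for metric in base:
        b, v = base[metric], var[metric]
        rows.append(
            {
                "metric": metric,
                "baseline": b,
                "variant": v,
                "absolute_change": v - b,
                "percent_change": 100.0 * (v - b) / b if b != 0.0 else float("nan"),
            }
        )
    return ScenarioComparison(
        baseline_label=baseline.label, variant_label=variant.label, table=pd.DataFrame(rows)
    )


def make_fixture(
    fractions: dict[str, float],
    n_droplets: int = 1000,
    seed: int = 0,
    dv50: float = 11.0,
    gsd: float = 1.57,
    density: float = 1000.0,
    lobe_fractions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Fabricate a deposition-record table with exact regional mass fractions.

    Droplet diameters are sampled from a lognormal; droplets are then dealt
    to regions approximately by mass and each region's masses are rescaled
    (diameters adjusted by the cube root) so that its share of the total mass
    matches the request *exactly*.  The remainder is split between exited
    (attributed to lobes per ``lobe_fractions``, default all LL) and
    airborne.  Reproducible under a fixed seed.
    """
    bad = {k: v for k, v in fractions.items() if v < 0.0}
    if bad:
        raise ValueError(f"negative fractions: {bad}")
    unknown = [k for k in fractions if k not in REGIONS]
    if unknown:
        raise KeyError(f"unknown region labels: {unknown}")
    total_frac = sum(fractions.values())
    if total_frac > 1.0 + 1e-12:
        raise ValueError(f"fractions sum to {total_frac}, must be <= 1")
    if n_droplets < len(fractions) + 1:
        raise ValueError("need at least one droplet per requested region plus remainder")

    rng = np.random.default_rng(seed)
    d = rng.lognormal(math.log(dv50), math.log(gsd), size=n_droplets)
    mass = density * math.pi * (d * 1e-6) ** 3 / 6.0
    total_mass = mass.sum()

    # Deal droplets into buckets: per-region plus a remainder bucket.
    labels = list(fractions)
    targets = [fractions[k] * total_mass for k in labels]
    remainder_target = total_mass - sum(targets)
    order = rng.permutation(n_droplets)
    buckets: list[list[int]] = [[] for _ in range(len(labels) + 1)]
    acc = np.zeros(len(labels) + 1)
    goals = np.array(targets + [remainder_target])
    share = np.where(goals > 0, goals, 0.0)
    for idx in order:
        # Put each droplet where the relative shortfall is largest.
        with np.errstate(divide="ignore", invalid="ignore"):
            shortfall = np.where(share > 0, (share - acc) / share, -np.inf)
        b = int(np.argmax(shortfall))
        buckets[b].append(idx)
        acc[b] += mass[idx]

    status = np.full(n_droplets, "airborne", dtype=object)
    region = np.full(n_droplets, "", dtype=object)
    lobe = np.full(n_droplets, "", dtype=object)
    outlet = np.full(n_droplets, -1, dtype=int)
    patch = np.full(n_droplets, "", dtype=object)

    # Rescale each bucket's masses to hit its target exactly (diameters move
    # by the cube root, so mass = rho pi d^3/6 stays consistent).
    for b, label in enumerate(labels):
        sel = np.array(buckets[b], dtype=int)
        if goals[b] > 0 and sel.size == 0:
            raise RuntimeError("empty bucket for a positive fraction; increase n_droplets")
        if sel.size:
            scale = goals[b] / mass[sel].sum() if goals[b] > 0 else 0.0
            if scale <= 0.0:
                # Zero-mass region request: drop these droplets into remainder.
                buckets[-1].extend(buckets[b])
                continue
            mass[sel] *= scale
            d[sel] *= scale ** (1.0 / 3.0)
            status[sel] = STATUS_DEPOSITED
            region[sel] = label
            patch[sel] = [f"{label}:0:{i % 10}" for i in range(sel.size)]

    rem = np.array(buckets[-1], dtype=int)
    if rem.size:
        if remainder_target <= 0.0:
            # Everything deposited: shrink remainder droplets to zero mass is
            # not allowed (masses must stay positive), so rescale them into
            # the last region instead.
            raise ValueError("fractions sum to 1 but droplets remain; use fewer droplets or sum < 1")
        scale = remainder_target / mass[rem].sum()
        mass[rem] *= scale
        d[rem] *= scale ** (1.0 / 3.0)
        # Half (by count) exit through lobar outlets, half stay airborne,
        # unless the caller asked for specific lobe shares of the exited mass.
        half = rem[: rem.size // 2] if rem.size > 1 else rem
        status[half] = STATUS_EXITED
        if lobe_fractions:
            lobes = list(lobe_fractions)
            probs = np.array([lobe_fractions[lb] for lb in lobes], dtype=float)
            probs = probs / probs.sum()
            lobe[half] = rng.choice(lobes, size=half.size, p=probs)
        else:
            lobe[half] = "LL"
        outlet[half] = 0

    records = pd.DataFrame(
        {
            "droplet_id": np.arange(n_droplets),
            "diameter_um": d,
            "mass_kg": mass,
            "status": status,
            "region": region,
            "generation": np.where(region == "TB", 0, -1),
            "lobe": lobe,
            "outlet_id": outlet,
            "fate_time_s": rng.uniform(0.0, 6.0, size=n_droplets),
            "patch_id": patch,
        }
    )[RECORD_COLUMNS]
    return records
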