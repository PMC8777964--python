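"""Polydisperse droplet source for a pressurized metered-dose inhaler (MDI).

Laser-diffraction instruments report the *volume-weighted* lognormal size
distribution of a spray: a volume median diameter (Dv50) and a geometric
standard deviation (GSD).  Individual droplets, however, are sampled one by
one (number-weighted), so the generator draws diameters from the *count*
lognormal obtained through the Hatch-Choate conversion

    CMD = Dv50 * exp(-3 * ln(GSD)**2)

which guarantees that the volume-weighted median of a large sample converges
to Dv50.  Diameters outside the configured bounds are rejected and redrawn,
which preserves the lognormal shape inside the bounds (no probability atoms
at the truncation limits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SizeDistributionSpec",
    "AirProperties",
    "SourceConfig",
    "Droplet",
    "DropletPopulation",
    "droplet_mass",
    "sample_sizes",
    "make_population",
    "volume_median",
    "volume_gsd",
]

#: Fixed column order for droplet-population CSV files.
POPULATION_COLUMNS = [
    "id",
    "diameter_um",
    "mass_kg",
    "release_time_s",
    "dir_x",
    "dir_y",
    "dir_z",
    "speed_m_s",
]


@dataclass(frozen=True)
class SizeDistributionSpec:
    """Truncated volume-lognormal droplet size distribution (diameters in µm)."""

    dv50: float = 11.0
    gsd: float = 1.57
    d_min: float = 0.5
    d_max: float = 35.0

    def __post_init__(self) -> None:
        if self.gsd < 1.0:
            raise ValueError(f"gsd must be >= 1, got {self.gsd}")
        if not (0.0 < self.d_min < self.dv50 < self.d_max):
            raise ValueError(
                "size bounds must satisfy 0 < d_min < dv50 < d_max, got "
                f"d_min={self.d_min}, dv50={self.dv50}, d_max={self.d_max}"
            )

    @property
    def sigma_ln(self) -> float:
        """Standard deviation of ln(diameter)."""
        return math.log(self.gsd)

    @property
    def count_median(self) -> float:
        """Count median diameter (µm) via the Hatch-Choate conversion."""
        return self.dv50 * math.exp(-3.0 * self.sigma_ln**2)


@dataclass(frozen=True)
class AirProperties:
    """Carrier-gas properties used by drag and settling formulas."""

    density: float = 1.204  # kg/m^3 at ~20 C
    viscosity: float = 1.81e-5  # Pa s
    gravity: float = 9.81  # m/s^2

    def __post_init__(self) -> None:
        if min(self.density, self.viscosity, self.gravity) <= 0.0:
            raise ValueError("air properties must be strictly positive")


@dataclass(frozen=True)
class SourceConfig:
    """Nozzle discharge configuration of the inhaler."""

    orifice_diameter_mm: float = 0.5
    discharge_speed: float = 40.0  # m/s along the nozzle axis
    plume_half_angle_deg: float = 10.0
    n_droplets: int = 100_000
    actuation_duration_s: float = 0.2
    droplet_density: float = 1000.0  # kg/m^3; deposition fractions are invariant to it
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.orifice_diameter_mm <= 0.0:
            raise ValueError("orifice diameter must be positive")
        if self.discharge_speed <= 0.0:
            raise ValueError("discharge speed must be positive")
        if not (0.0 <= self.plume_half_angle_deg < 90.0):
            raise ValueError("plume half angle must be in [0, 90) degrees")
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.actuation_duration_s <= 0.0:
            raise ValueError("actuation duration must be positive")
        if self.droplet_density <= 0.0:
            raise ValueError("droplet density must be positive")


@dataclass(frozen=True)
class Droplet:
    """A single discharged droplet."""

    id: int
    diameter_um: float
    density: float
    mass_kg: float
    release_time_s: float
    initial_speed: float
    direction: tuple[float, float, float]


def droplet_mass(diameter_um, density: float = 1000.0):
    """Mass (kg) of a spherical droplet of the given diameter (µm) and density.

    ``mass = density * pi * d^3 / 6`` with the diameter converted to metres.
    A zero diameter is accepted as the boundary limit (mass 0); negative
    diameters and non-positive densities are rejected.
    """
    d = np.asarray(diameter_um, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("diameter must be non-negative")
    if density <= 0.0:
        raise ValueError("density must be positive")
    mass = density * math.pi * (d * 1e-6) ** 3 / 6.0
    return float(mass) if np.isscalar(diameter_um) else mass


def sample_sizes(spec: SizeDistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` droplet diameters (µm) from the truncated size distribution.

    Sampling is number-weighted from the count lognormal implied by the
    volume-lognormal parameters; out-of-bounds draws are rejected and redrawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.gsd == 1.0:
        return np.full(n, spec.dv50, dtype=float)
    mu = math.log(spec.count_median)
    sigma = spec.sigma_ln
    out = np.empty(n, dtype=float)
    filled = 0
    # Rejection loop: the acceptance probability is high for the default
    # bounds, so a handful of batches suffices.
    while filled < n:
        draw = rng.lognormal(mean=mu, sigma=sigma, size=max(n - filled, 1024))
        keep = draw[(draw >= spec.d_min) & (draw <= spec.d_max)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def volume_median(diameters_um: np.ndarray) -> float:
    """Empirical volume-weighted median diameter (µm) of a sample."""
    d = np.sort(np.asarray(diameters_um, dtype=float))
    if d.size == 0:
        raise ValueError("empty sample")
    w = d**3
    cum = np.cumsum(w) / w.sum()
    return float(np.interp(0.5, cum, d))


def volume_gsd(diameters_um: np.ndarray) -> float:
    """Empirical GSD of the volume-weighted size distribution of a sample."""
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        raise ValueError("empty sample")
    w = d**3
    ln_d = np.log(d)
    mean = np.average(ln_d, weights=w)
    var = np.average((ln_d - mean) ** 2, weights=w)
    return float(math.exp(math.sqrt(var)))


def _cone_directions(n: int, half_angle_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Unit vectors uniformly distributed (by solid angle) in a cone about +x."""
    if half_angle_deg == 0.0:
        out = np.zeros((n, 3))
        out[:, 0] = 1.0
        return out
    cos_max = math.cos(math.radians(half_angle_deg))
    cos_t = rng.uniform(cos_max, 1.0, size=n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    psi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([cos_t, sin_t * np.cos(psi), sin_t * np.sin(psi)])


@dataclass
class DropletPopulation:
    """Arrays describing one discharged droplet cloud."""

    ids: np.ndarray
    diameters_um: np.ndarray
    masses_kg: np.ndarray
    release_times_s: np.ndarray
    directions: np.ndarray  # (n, 3) unit vectors
    speeds: np.ndarray  # m/s, magnitude at release
    density: float = 1000.0

    def __len__(self) -> int:
        return self.ids.size

    @property
    def total_mass(self) -> float:
        return float(self.masses_kg.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "diameter_um": self.diameters_um,
                "mass_kg": self.masses_kg,
                "release_time_s": self.release_times_s,
                "dir_x": self.directions[:, 0],
                "dir_y": self.directions[:, 1],
                "dir_z": self.directions[:, 2],
                "speed_m_s": self.speeds,
            }
        )[POPULATION_COLUMNS]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, density: float = 1000.0) -> "DropletPopulation":
        missing = [c for c in POPULATION_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"population table missing columns: {missing}")
        return cls(
            ids=frame["id"].to_numpy(dtype=int),
            diameters_um=frame["diameter_um"].to_numpy(dtype=float),
            masses_kg=frame["mass_kg"].to_numpy(dtype=float),
            release_times_s=frame["release_time_s"].to_numpy(dtype=float),
            directions=frame[["dir_x", "dir_y", "dir_z"]].to_numpy(dtype=float),
            speeds=frame["speed_m_s"].to_numpy(dtype=float),
            density=density,
        )

    @classmethod
    def from_csv(cls, path, density: float = 1000.0) -> "DropletPopulation":
        return cls.from_frame(pd.read_csv(path), density=density)


def make_population(
    src: SourceConfig,
    spec: SizeDistributionSpec | None = None,
    rng: np.random.Generator | None = None,
) -> DropletPopulation:
    """Generate the droplet cloud discharged during one actuation.

    Release times are uniform over the actuation step, directions uniform in
    the plume cone about the nozzle axis (+x) and every droplet leaves at the
    configured discharge speed.
    """
    spec = spec if spec is not None else SizeDistributionSpec()
    rng = rng if rng is not None else np.random.default_rng(src.rng_seed)
    n = src.n_droplets
    diameters = sample_sizes(spec, n, rng)
    release = rng.uniform(0.0, src.actuation_duration_s, size=n)
    directions = _cone_directions(n, src.plume_half_angle_deg, rng)
    return DropletPopulation(
        ids=np.arange(n, dtype=int),
        diameters_um=diameters,
        masses_kg=droplet_mass(diameters, src.droplet_density),
        release_times_s=release,
        directions=directions,
        speeds=np.full(n, src.discharge_speed, dtype=float),
        density=src.droplet_density,
    )
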