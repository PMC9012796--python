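"""Injection model for the high-pressure nebulizer nozzle.

Covers the nozzle exit speed, the flow-rate dependence of the spray cone
angle and of the measured volume-median droplet diameter, the impaction
parameter d_p^2*Q, and stochastic sampling of injection ensembles (emission
times, droplet diameters, initial velocity directions on the spray cone).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import CavityGeometry, SimulationConfig

__all__ = [
    "DropletSizeSpec",
    "ConeModel",
    "initial_speed",
    "impaction_parameter",
    "median_diameter_for_flow_rate",
    "cone_angle",
    "sample_injection",
    "InjectionSchedule",
    "MEDIAN_DIAMETER_TABLE",
]

#: Measured volume-median diameter D(v,0.5) [um] vs. liquid flow rate [mL/s]
#: for the clinical 200 um nozzle at 20 bar maximum upstream pressure.
MEDIAN_DIAMETER_TABLE = {
    0.4: 48.0,
    0.5: 40.0,
    0.6: 35.0,
    0.7: 29.0,
    0.8: 28.0,
    0.9: 28.0,
}

#: Laser-diffraction lens working range [um]; diameters outside are rejected.
_INSTRUMENT_RANGE_UM = (0.5, 900.0)


@dataclass(frozen=True)
class DropletSizeSpec:
    """Droplet size distribution: monodisperse or lognormal.

    For the lognormal mode ``median`` is the *volume*-median diameter
    D(v,0.5) in um with geometric standard deviation ``gsd``; the underlying
    number distribution is derived via the Hatch-Choate relation
    d_g(number) = D(v,0.5) * exp(-3 ln^2 gsd).
    """

    mode: str  # "monodisperse" | "lognormal"
    median: float  # um (droplet diameter for monodisperse)
    gsd: float = 1.0

    def __post_init__(self):
        if self.mode not in ("monodisperse", "lognormal"):
            raise ValueError(f"unknown PSD mode {self.mode!r}")
        lo, hi = _INSTRUMENT_RANGE_UM
        if not (lo < self.median < hi):
            raise ValueError(
                f"diameter {self.median} um outside instrument range ({lo}, {hi})"
            )
        if self.mode == "lognormal" and self.gsd <= 1.0:
            raise ValueError("lognormal gsd must exceed 1")

    @classmethod
    def monodisperse(cls, diameter_um: float) -> "DropletSizeSpec":
        return cls("monodisperse", diameter_um)

    @classmethod
    def lognormal(cls, volume_median_um: float, gsd: float = 1.5) -> "DropletSizeSpec":
        return cls("lognormal", volume_median_um, gsd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n diameters [m]."""
        if self.mode == "monodisperse":
            return np.full(n, self.median * 1e-6)
        ln_gsd = math.log(self.gsd)
        number_median = self.median * math.exp(-3.0 * ln_gsd**2)
        d_um = np.exp(rng.normal(math.log(number_median), ln_gsd, size=n))
        return np.clip(d_um, *_INSTRUMENT_RANGE_UM) * 1e-6

    def to_dict(self) -> dict:
        return {"mode": self.mode, "median": self.median, "gsd": self.gsd}

    @classmethod
    def from_dict(cls, d: dict) -> "DropletSizeSpec":
        return cls(d["mode"], d["median"], d.get("gsd", 1.0))


@dataclass(frozen=True)
class ConeModel:
    """Saturating spray-cone-angle law alpha(Q) = alpha_max - c * exp(-k Q).

    The default calibration rises from narrow cones at low flow rate to a
    ~71 deg plateau, passing ~70 deg at the clinical 0.5-0.6 mL/s.  The
    coefficients of the published experimental curve fit are retained as data
    via :meth:`as_printed` but are not the default (the printed fit does not
    evaluate to the ~70 deg anchor).
    """

    alpha_max: float = 71.0  # degrees
    c: float = 65.0  # degrees
    k: float = 8.45  # s mL^-1
    fixed_angle: float | None = None  # degrees; overrides the law if set

    @classmethod
    def fixed(cls, angle_deg: float) -> "ConeModel":
        return cls(fixed_angle=angle_deg)

    @classmethod
    def as_printed(cls) -> tuple[float, float, float]:
        """Coefficients (a, b, k) of the published fit a + b*exp(-k*Q)."""
        return (-103.59, 175.96, 8.45)

    def angle(self, flow_rate: float) -> float:
        if flow_rate <= 0:
            raise ValueError("flow rate must be positive")
        if self.fixed_angle is not None:
            return self.fixed_angle
        a = self.alpha_max - self.c * math.exp(-self.k * flow_rate)
        if not (0.0 < a < 180.0):
            raise ValueError(f"cone angle {a:.1f} deg outside (0, 180)")
        return a


def initial_speed(flow_rate: float, orifice_diameter: float) -> float:
    """Nozzle exit speed u0 = Q / A_O [m/s].

    ``flow_rate`` in mL/s, ``orifice_diameter`` in m.  0.5 mL/s through the
    200 um clinical orifice gives 15.92 m/s.
    """
    if flow_rate < 0 or orifice_diameter <= 0:
        raise ValueError("flow rate must be >= 0 and orifice diameter > 0")
    area = math.pi * orifice_diameter**2 / 4.0
    return (flow_rate * 1e-6) / area


def impaction_parameter(diameter_um, flow_rate):
    """Inertial impaction parameter d_p^2 * Q [um^2 mL/s].

    Integer truncation of the result reproduces the published six-case table.
    """
    return np.asarray(diameter_um, dtype=float) ** 2 * np.asarray(flow_rate, dtype=float)


def median_diameter_for_flow_rate(flow_rate: float) -> float:
    """Measured D(v,0.5) [um] for a flow rate within the calibrated range.

    Linear interpolation between the measured knots (0.4..0.9 mL/s);
    extrapolation is refused as out-of-calibration.
    """
    knots = sorted(MEDIAN_DIAMETER_TABLE)
    if not (knots[0] <= flow_rate <= knots[-1]):
        raise ValueError(
            f"flow rate {flow_rate} mL/s outside calibrated range "
            f"[{knots[0]}, {knots[-1]}]"
        )
    return float(
        np.interp(flow_rate, knots, [MEDIAN_DIAMETER_TABLE[q] for q in knots])
    )


def cone_angle(flow_rate: float, model: ConeModel | None = None) -> float:
    """Spray cone (full) angle [degrees] at the given flow rate."""
    return (model or ConeModel()).angle(flow_rate)


def _cap_directions(
    axis: np.ndarray, half_angle_rad: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit vectors uniform over the spherical cap of the given half-angle."""
    cos_min = math.cos(half_angle_rad)
    cos_t = rng.uniform(cos_min, 1.0, size=n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    # local frame with e3 = axis
    e3 = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(e3 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(e3, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    return (
        np.outer(sin_t * np.cos(phi), e1)
        + np.outer(sin_t * np.sin(phi), e2)
        + np.outer(cos_t, e3)
    )


@dataclass(frozen=True)
class InjectionSchedule:
    """Sampled injection ensemble: one row per parcel (= physical droplet)."""

    emission_times: np.ndarray  # s
    diameters: np.ndarray  # m
    velocities: np.ndarray  # (n, 3) m/s

    def __len__(self):
        return len(self.emission_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "emission_time_s": self.emission_times,
                "diameter_m": self.diameters,
                "vx_m_per_s": self.velocities[:, 0],
                "vy_m_per_s": self.velocities[:, 1],
                "vz_m_per_s": self.velocities[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_injection(
    config: SimulationConfig,
    n_parcels: int | None = None,
    seed: int | None = None,
    geometry: CavityGeometry | None = None,
    cone_model: ConeModel | None = None,
) -> InjectionSchedule:
    """Sample emission times, diameters and initial velocities for a run.

    Emission times are uniform over [0, volume/Q]; directions are uniform over
    the solid-angle cap of half the cone angle about the nozzle axis; speeds
    equal the nozzle exit speed.  Reproducible for a fixed seed.
    """
    n = config.n_parcels if n_parcels is None else n_parcels
    if n < 0:
        raise ValueError("n_parcels must be >= 0")
    if n == 0:
        import warnings

        warnings.warn("empty injection schedule requested", stacklevel=2)
        return InjectionSchedule(np.empty(0), np.empty(0), np.empty((0, 3)))
    geometry = geometry or CavityGeometry()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    times = np.sort(rng.uniform(0.0, config.injection_duration, size=n))
    diameters = config.droplet_spec.sample(n, rng)
    if config.cone_angle is not None:
        full_angle = config.cone_angle
    else:
        full_angle = cone_angle(config.flow_rate, cone_model)
    u0 = initial_speed(config.flow_rate, config.orifice_diameter)
    dirs = _cap_directions(
        geometry.nozzle_direction, math.radians(full_angle / 2.0), n, rng
    )
    return InjectionSchedule(times, diameters, u0 * dirs)
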