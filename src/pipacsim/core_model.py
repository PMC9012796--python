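"""Domain types, unit conversions and geometry queries for the PIPAC box cavity.

The simulated system is a CO2-insufflated rectangular cavity (an in-vitro
stand-in for the pneumoperitoneum) into which a drug-carrying liquid is
nebulized from a nozzle at the centre of the top face.  All internal
computation is SI; practical units (mL/s, µm, mmHg, kV) are converted exactly
once at the interface.

Coordinate convention: right-handed, gravity along -z, origin at the centre of
the bottom face.  x spans ±Lx/2, y spans ±Ly/2, z spans [0, H].  The nozzle
sits at (0, 0, H) pointing straight down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .nebulizer import DropletSizeSpec

__all__ = [
    "MMHG_TO_PA",
    "GRAVITY",
    "TissuePlate",
    "CavityGeometry",
    "GasProperties",
    "LiquidProperties",
    "SimulationConfig",
    "convert_pressure",
    "classify_region",
    "gas_dynamic_viscosity",
    "INK",
    "SALINE",
    "ICODEXTRIN_4",
    "ICODEXTRIN_75",
]

#: Exact conversion factor between mmHg and pascal.
MMHG_TO_PA = 133.322

#: Gravitational acceleration magnitude [m s^-2].
GRAVITY = 9.81

#: Wall identifiers in the order used by distance queries.
WALL_IDS = ("x-", "x+", "y-", "y+", "bottom", "top")


def convert_pressure(value_mmhg):
    """Convert an insufflation pressure from mmHg to Pa (1 mmHg = 133.322 Pa).

    Accepts scalars or arrays; negative pressures are rejected.
    """
    arr = np.asarray(value_mmhg, dtype=float)
    if np.any(arr < 0):
        raise ValueError("pressure in mmHg must be non-negative")
    out = arr * MMHG_TO_PA
    return float(out) if np.isscalar(value_mmhg) or out.ndim == 0 else out


def _orthonormal_tangents(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane basis for a plate with the given unit normal."""
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


@dataclass(frozen=True)
class TissuePlate:
    """A grounded metal plate carrying a tissue sample on a cavity surface.

    ``half_extents`` are the in-plane half-widths of the (rectangular) sample,
    default 10 x 10 mm for a 20 x 20 mm tissue patch.
    """

    label: str
    center: np.ndarray
    normal: np.ndarray
    half_extents: np.ndarray = field(
        default_factory=lambda: np.array([0.010, 0.010])
    )
    grounded: bool = True

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plate normal must be nonzero")
        object.__setattr__(self, "normal", n / norm)
        he = np.asarray(self.half_extents, dtype=float)
        if he.shape != (2,) or np.any(he <= 0):
            raise ValueError("half_extents must be two positive lengths")
        object.__setattr__(self, "half_extents", he)

    def local_coords(self, points: np.ndarray) -> np.ndarray:
        """Project points onto the plate plane, returning (N, 2) in-plane coords."""
        t1, t2 = _orthonormal_tangents(self.normal)
        d = np.atleast_2d(points) - self.center
        return np.stack([d @ t1, d @ t2], axis=-1)

    def covers(self, points: np.ndarray, tol: float = 1e-3) -> np.ndarray:
        """True where a (deposited) point lies on the plate footprint.

        ``tol`` is the allowed off-plane distance; deposits sit up to one
        droplet diameter off the wall surface, so a 1 mm default is ample.
        """
        pts = np.atleast_2d(points)
        off_plane = np.abs((pts - self.center) @ self.normal)
        uv = self.local_coords(pts)
        inside = (
            (off_plane <= tol)
            & (np.abs(uv[:, 0]) <= self.half_extents[0])
            & (np.abs(uv[:, 1]) <= self.half_extents[1])
        )
        return inside if pts.shape[0] > 1 else inside


def _default_plates(extents: np.ndarray) -> list[TissuePlate]:
    """Plates A-D: two on the bottom, one on the left side wall, one on top."""
    lx, ly, h = extents
    return [
        TissuePlate("A", center=(0.0, 0.0, 0.0), normal=(0, 0, 1)),
        TissuePlate("B", center=(-0.055, 0.0, 0.0), normal=(0, 0, 1)),
        TissuePlate("C", center=(-lx / 2, 0.0, h / 2), normal=(1, 0, 0)),
        TissuePlate("D", center=(-0.040, 0.0, h), normal=(0, 0, -1)),
    ]


@dataclass(frozen=True)
class CavityGeometry:
    """The insufflated box cavity, its nozzle pose, tissue plates and regions.

    Regions 1..region_count are equal-thickness horizontal slabs along z,
    region 1 at the bottom (dorsal, opposite the nozzle) and the last at the
    top (ventral).
    """

    extents: np.ndarray = field(
        default_factory=lambda: np.array([0.185, 0.135, 0.152])
    )
    nozzle_position: np.ndarray | None = None
    nozzle_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -1.0])
    )
    plates: tuple[TissuePlate, ...] | None = None
    region_count: int = 4

    def __post_init__(self):
        ext = np.asarray(self.extents, dtype=float)
        if ext.shape != (3,) or np.any(ext <= 0):
            raise ValueError("extents must be three positive lengths")
        object.__setattr__(self, "extents", ext)
        if self.nozzle_position is None:
            pos = np.array([0.0, 0.0, ext[2]])
        else:
            pos = np.asarray(self.nozzle_position, dtype=float)
        object.__setattr__(self, "nozzle_position", pos)
        direction = np.asarray(self.nozzle_direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        object.__setattr__(self, "nozzle_direction", direction)
        if self.plates is None:
            plates = tuple(_default_plates(ext))
        else:
            plates = tuple(self.plates)
        labels = [p.label for p in plates]
        if len(set(labels)) != len(labels):
            raise ValueError("plate labels must be unique")
        object.__setattr__(self, "plates", plates)
        if self.region_count < 1:
            raise ValueError("region_count must be >= 1")
        if np.min(self.wall_distance(pos[None, :])) > 1e-9:
            raise ValueError("nozzle_position must lie on the cavity boundary")
        for p in plates:
            if np.min(self.wall_distance(p.center[None, :])) > 1e-9 and not self.contains(
                p.center[None, :]
            )[0]:
                raise ValueError(f"plate {p.label} lies outside the cavity")

    # -- geometry queries ---------------------------------------------------

    @property
    def half_xy(self) -> np.ndarray:
        return self.extents[:2] / 2.0

    @property
    def height(self) -> float:
        return float(self.extents[2])

    @property
    def volume(self) -> float:
        return float(np.prod(self.extents))

    def contains(self, points: np.ndarray, tol: float = 1e-12) -> np.ndarray:
        pts = np.atleast_2d(points)
        hx, hy = self.half_xy
        return (
            (np.abs(pts[:, 0]) <= hx + tol)
            & (np.abs(pts[:, 1]) <= hy + tol)
            & (pts[:, 2] >= -tol)
            & (pts[:, 2] <= self.height + tol)
        )

    def wall_distances(self, points: np.ndarray) -> np.ndarray:
        """Signed distances to the six walls, shape (N, 6), negative outside.

        Column order follows ``WALL_IDS``: x-, x+, y-, y+, bottom, top.
        """
        pts = np.atleast_2d(points)
        hx, hy = self.half_xy
        return np.stack(
            [
                pts[:, 0] + hx,
                hx - pts[:, 0],
                pts[:, 1] + hy,
                hy - pts[:, 1],
                pts[:, 2],
                self.height - pts[:, 2],
            ],
            axis=1,
        )

    def wall_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the nearest wall (negative outside)."""
        return self.wall_distances(points).min(axis=1)

    def nearest_wall(self, points: np.ndarray) -> np.ndarray:
        """Index into WALL_IDS of the nearest wall for each point."""
        return self.wall_distances(points).argmin(axis=1)

    def plate_at(self, point: np.ndarray) -> TissuePlate | None:
        for p in self.plates:
            if p.covers(point[None, :])[0]:
                return p
        return None

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "extents": self.extents.tolist(),
                "nozzle_position": self.nozzle_position.tolist(),
                "nozzle_direction": self.nozzle_direction.tolist(),
                "region_count": self.region_count,
                "plates": [
                    {
                        "label": p.label,
                        "center": p.center.tolist(),
                        "normal": p.normal.tolist(),
                        "half_extents": p.half_extents.tolist(),
                        "grounded": p.grounded,
                    }
                    for p in self.plates
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CavityGeometry":
        d = json.loads(text)
        plates = tuple(
            TissuePlate(
                label=p["label"],
                center=np.array(p["center"]),
                normal=np.array(p["normal"]),
                half_extents=np.array(p["half_extents"]),
                grounded=p["grounded"],
            )
            for p in d["plates"]
        )
        return cls(
            extents=np.array(d["extents"]),
            nozzle_position=np.array(d["nozzle_position"]),
            nozzle_direction=np.array(d["nozzle_direction"]),
            plates=plates,
            region_count=d["region_count"],
        )


def classify_region(points: np.ndarray, geometry: CavityGeometry) -> np.ndarray:
    """Map interior points to dorsal->ventral regions 1..region_count.

    Regions are equal-thickness horizontal slabs; slab boundaries are
    lower-inclusive, so a point at exactly half cavity height (with 4 regions)
    falls in region 3.  The top face maps to the last region.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(geometry.contains(pts, tol=1e-9)):
        raise ValueError("point outside cavity")
    slab = geometry.height / geometry.region_count
    region = 1 + np.floor(pts[:, 2] / slab).astype(int)
    region = np.minimum(region, geometry.region_count)
    return region if np.asarray(points).ndim > 1 else int(region[0])


@dataclass(frozen=True)
class GasProperties:
    """CO2 insufflation gas at 12 mmHg and room temperature."""

    density: float = 1.977  # kg m^-3
    kinematic_viscosity: float = 7.44e-6  # m^2 s^-1
    pressure: float = 1600.0  # Pa

    def __post_init__(self):
        if self.density <= 0 or self.kinematic_viscosity < 0 or self.pressure <= 0:
            raise ValueError("gas properties must be positive")

    @property
    def dynamic_viscosity(self) -> float:
        """mu = rho * nu [Pa s]."""
        return self.density * self.kinematic_viscosity


def gas_dynamic_viscosity(gas: GasProperties) -> float:
    """Dynamic viscosity of the carrier gas, rho0 * nu [Pa s]."""
    return gas.dynamic_viscosity


@dataclass(frozen=True)
class LiquidProperties:
    """Nebulized carrier liquid.

    ``dynamic_viscosity`` is in mPa s as customarily reported for these
    solutions; ``surface_tension`` [N/m] enters only the Weber-number
    diagnostic.
    """

    name: str
    density: float  # kg m^-3
    dynamic_viscosity: float  # mPa s
    surface_tension: float = 0.072  # N m^-1

    def __post_init__(self):
        if min(self.density, self.dynamic_viscosity, self.surface_tension) <= 0:
            raise ValueError("liquid properties must be positive")


#: Black drawing ink used for the deposition experiments.
INK = LiquidProperties("ink", density=1070.0, dynamic_viscosity=2.1,
                       surface_tension=0.050)
#: 0.9 % NaCl.
SALINE = LiquidProperties("saline", density=1005.0, dynamic_viscosity=1.0,
                          surface_tension=0.072)
#: Icodextrin glucose-polymer carrier solutions.
ICODEXTRIN_4 = LiquidProperties("icodextrin 4%", density=1016.0,
                                dynamic_viscosity=1.88, surface_tension=0.068)
ICODEXTRIN_75 = LiquidProperties("icodextrin 7.5%", density=1028.0,
                                 dynamic_viscosity=2.24, surface_tension=0.067)

_LIQUID_PRESETS = {
    liq.name: liq for liq in (INK, SALINE, ICODEXTRIN_4, ICODEXTRIN_75)
}


@dataclass(frozen=True)
class SimulationConfig:
    """A single nebulization run.

    Practical units at the interface: flow rate in mL/s, volume in mL,
    voltage magnitude in kV (0 selects plain PIPAC), charge in coulomb.
    """

    flow_rate: float = 0.5  # mL s^-1
    nebulized_volume: float = 20.0  # mL
    orifice_diameter: float = 200e-6  # m
    droplet_spec: "DropletSizeSpec | None" = None
    cone_angle: float | None = None  # degrees; None -> from ConeModel
    total_time: float = 1800.0  # s
    injection_timestep: float = 0.001  # s
    voltage: float = 0.0  # kV, magnitude; 0 = PIPAC
    droplet_charge: float = -5e-14  # C; corona-charging (Pauthenier) scale
    seed: int = 0
    liquid: LiquidProperties = INK
    n_parcels: int = 10000
    flow_model: str = "quiescent"  # or "round_jet"

    def __post_init__(self):
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if self.injection_timestep <= 0:
            raise ValueError("injection_timestep must be positive")
        if self.injection_duration > self.total_time:
            raise ValueError("injection duration exceeds total simulation time")
        if abs(self.voltage) > 10.0:
            raise ValueError("voltage magnitude limited to 10 kV (supply range)")
        if self.droplet_spec is None:
            from .nebulizer import DropletSizeSpec

            object.__setattr__(
                self, "droplet_spec", DropletSizeSpec.monodisperse(30.0)
            )

    @property
    def injection_duration(self) -> float:
        """Emission window volume/Q [s]; 20 mL at 0.5 mL/s -> 40 s."""
        return self.nebulized_volume / self.flow_rate

    @property
    def flow_rate_si(self) -> float:
        """Volumetric flow rate [m^3 s^-1]."""
        return self.flow_rate * 1e-6

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "flow_rate": self.flow_rate,
            "nebulized_volume": self.nebulized_volume,
            "orifice_diameter": self.orifice_diameter,
            "droplet_spec": self.droplet_spec.to_dict(),
            "cone_angle": self.cone_angle,
            "total_time": self.total_time,
            "injection_timestep": self.injection_timestep,
            "voltage": self.voltage,
            "droplet_charge": self.droplet_charge,
            "seed": self.seed,
            "liquid": self.liquid.name,
            "n_parcels": self.n_parcels,
            "flow_model": self.flow_model,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        from .nebulizer import DropletSizeSpec

        d = dict(d)
        if "droplet_spec" in d and isinstance(d["droplet_spec"], dict):
            d["droplet_spec"] = DropletSizeSpec.from_dict(d["droplet_spec"])
        if "liquid" in d and isinstance(d["liquid"], str):
            d["liquid"] = _LIQUID_PRESETS[d["liquid"]]
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        import yaml

        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        import yaml

        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d)
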