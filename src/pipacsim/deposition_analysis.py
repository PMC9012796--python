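"""Quantitative read-outs of a transport run.

Three observables mirror the experimental workflow: the percentage of
injected droplets depositing in each dorsal-to-ventral region; the stained
proportion of each tissue plate (a computational analogue of photographing
the plate and thresholding in ImageJ -- each deposit is stamped as a disc of
``footprint_scale`` times its airborne radius onto a raster); and a scalar
homogeneity index 1 - CV/sqrt(3) over the four region fractions, which is 1
for perfectly even deposition and 0 when all mass lands in one region
(CV of a single-occupied 4-vector is sqrt(3), the maximum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core_model import CavityGeometry, TissuePlate, classify_region
from .droplet_transport import TransportRecords

__all__ = [
    "DepositionReport",
    "region_fractions",
    "plate_staining",
    "plate_raster",
    "homogeneity_index",
    "build_report",
]

#: Spread factor from airborne droplet diameter to stain footprint diameter.
DEFAULT_FOOTPRINT_SCALE = 10.0
#: Raster cell size for the staining analysis [m].
DEFAULT_RASTER_RESOLUTION = 50e-6


def region_fractions(
    records: TransportRecords, geometry: CavityGeometry
) -> np.ndarray:
    """Percentage of *injected* droplets deposited in each region (1..k).

    Computed over injected rather than deposited droplets so that runs with
    different airborne remainders stay comparable; the remainder is
    100 - sum(fractions).
    """
    if len(records) == 0:
        raise ValueError("no transport records")
    out = np.zeros(geometry.region_count)
    if records.n_deposited:
        regions = classify_region(records.deposit_positions(), geometry)
        counts = np.bincount(regions, minlength=geometry.region_count + 1)[1:]
        out = 100.0 * counts / len(records)
    return out


def homogeneity_index(fractions) -> float:
    """1 - CV/sqrt(3) over the four region fractions, clipped to [0, 1]."""
    f = np.asarray(fractions, dtype=float)
    if np.all(f == 0):
        raise ValueError("all-zero region fractions")
    if f.sum() > 100.0 + 1e-6:
        raise ValueError("region fractions exceed 100%")
    cv = f.std() / f.mean()
    return float(np.clip(1.0 - cv / np.sqrt(3.0), 0.0, 1.0))


def plate_raster(
    records: TransportRecords,
    plate: TissuePlate,
    raster_resolution: float = DEFAULT_RASTER_RESOLUTION,
    footprint_scale: float = DEFAULT_FOOTPRINT_SCALE,
) -> np.ndarray:
    """Boolean stain raster of the plate (True = covered cell)."""
    if raster_resolution >= min(plate.half_extents):
        raise ValueError("raster resolution must be finer than the plate")
    hx, hy = plate.half_extents
    nx = int(np.ceil(2 * hx / raster_resolution))
    ny = int(np.ceil(2 * hy / raster_resolution))
    raster = np.zeros((nx, ny), dtype=bool)
    on_plate = records.plate_labels == plate.label
    if not on_plate.any():
        return raster
    uv = plate.local_coords(records.final_positions[on_plate])
    radii = footprint_scale * records.diameters[on_plate] / 2.0
    xc = (np.arange(nx) + 0.5) * raster_resolution - hx
    yc = (np.arange(ny) + 0.5) * raster_resolution - hy
    for (u, v), r in zip(uv, radii):
        i0 = np.searchsorted(xc, u - r)
        i1 = np.searchsorted(xc, u + r, side="right")
        j0 = np.searchsorted(yc, v - r)
        j1 = np.searchsorted(yc, v + r, side="right")
        if i0 >= i1 or j0 >= j1:
            # footprint smaller than a cell: mark the containing cell
            i0 = np.clip(np.searchsorted(xc, u) - 0, 0, nx - 1)
            j0 = np.clip(np.searchsorted(yc, v) - 0, 0, ny - 1)
            raster[i0, j0] = True
            continue
        sub_x = xc[i0:i1]
        sub_y = yc[j0:j1]
        dist2 = (sub_x[:, None] - u) ** 2 + (sub_y[None, :] - v) ** 2
        raster[i0:i1, j0:j1] |= dist2 <= r**2
    return raster


def plate_staining(
    records: TransportRecords,
    plate: TissuePlate,
    raster_resolution: float = DEFAULT_RASTER_RESOLUTION,
    footprint_scale: float = DEFAULT_FOOTPRINT_SCALE,
) -> float:
    """Stained proportion of the plate [%]: covered cells / total cells."""
    raster = plate_raster(records, plate, raster_resolution, footprint_scale)
    return 100.0 * raster.sum() / raster.size


@dataclass(frozen=True)
class DepositionReport:
    """Per-run summary: region fractions, plate staining, homogeneity."""

    region_pct: tuple  # percentages, region 1..k
    airborne_pct: float
    plate_pct: dict  # label -> stained %
    homogeneity: float
    peak_phi: float = 0.0

    def to_dict(self) -> dict:
        return {
            "region_pct": list(self.region_pct),
            "airborne_pct": self.airborne_pct,
            "plate_pct": dict(self.plate_pct),
            "homogeneity": self.homogeneity,
            "peak_phi": self.peak_phi,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_report(
    records: TransportRecords,
    geometry: CavityGeometry,
    raster_resolution: float = DEFAULT_RASTER_RESOLUTION,
    footprint_scale: float = DEFAULT_FOOTPRINT_SCALE,
) -> DepositionReport:
    """Compute the full deposition report for one run."""
    fractions = region_fractions(records, geometry)
    homog = (
        homogeneity_index(fractions) if np.any(fractions > 0) else float("nan")
    )
    airborne = 100.0 * records.n_airborne / len(records)
    plates = {
        p.label: plate_staining(records, p, raster_resolution, footprint_scale)
        for p in geometry.plates
    }
    return DepositionReport(
        region_pct=tuple(fractions),
        airborne_pct=airborne,
        plate_pct=plates,
        homogeneity=homog,
        peak_phi=records.peak_volume_fraction(geometry),
    )
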