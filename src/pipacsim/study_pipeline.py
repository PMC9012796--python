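"""Parameter-study orchestration: sweeps, reference fixtures, exports.

Drives the simulator over the four study axes (droplet diameter, liquid flow
rate, carrier-liquid viscosity, electrode voltage), one deposition report per
(value, replicate).  Embeds the measured reference data (impaction-parameter
table, D(v,0.5)-flow-rate pairs, carrier viscosities, cone-angle anchors,
voltage series) used by the validation checks and the fixture generator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    ICODEXTRIN_4,
    ICODEXTRIN_75,
    SALINE,
    CavityGeometry,
    GasProperties,
    LiquidProperties,
    SimulationConfig,
)
from .deposition_analysis import DepositionReport, build_report
from .droplet_transport import TransportRecords, simulate
from .electrostatics import ElectrodeConfig, PotentialGrid, solve_potential
from .nebulizer import (
    MEDIAN_DIAMETER_TABLE,
    DropletSizeSpec,
    impaction_parameter,
    sample_injection,
)

__all__ = [
    "ReferenceFixtures",
    "SweepSpec",
    "run_single",
    "run_sweep",
    "reproduce_table1",
    "generate_fixture_ensemble",
    "export_results",
    "DEFAULT_SWEEP_GRIDS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceFixtures:
    """Embedded measured reference values for validation and fixtures.

    ``table1`` rows are (case, Q [mL/s], d_p [um], printed d_p^2*Q).
    ``median_diameters`` maps Q to (D(v,0.5) [um], SD [um]).
    """

    table1: tuple = (
        (1, 0.4, 48.0, 921),
        (2, 0.5, 40.0, 800),
        (3, 0.6, 35.0, 735),
        (4, 0.7, 29.0, 588),
        (5, 0.8, 28.0, 627),
        (6, 0.9, 28.0, 705),
    )
    median_diameters: tuple = (
        (0.4, 48.0, 2.0),
        (0.5, 40.0, 1.0),
        (0.6, 35.0, 2.0),
        (0.7, 29.0, 2.0),
        (0.8, 28.0, 2.0),
        (0.9, 28.0, 3.0),
    )
    viscosities_mPas: tuple = (("saline", 1.0), ("icodextrin 4%", 1.88),
                               ("icodextrin 7.5%", 2.24))
    cone_angle_anchor: tuple = (0.5, 70.0)  # (Q [mL/s], angle [deg])
    voltage_series_kV: tuple = (4.0, 5.0, 6.0, 6.5, 7.0, 8.0, 9.0)


#: Default sweep grids mirroring the parameter study.
DEFAULT_SWEEP_GRIDS = {
    "droplet_diameter": [1.0, 5.0, 10.0, 30.0, 50.0],  # um
    "flow_rate": [0.4, 0.5, 0.6, 0.7, 0.8, 0.9],  # mL/s
    "viscosity": [1.0, 1.88, 2.24],  # mPa s
    "voltage": [0.0, 4.0, 5.0, 6.0, 6.5, 7.0, 8.0, 9.0],  # kV
}

_VISCOSITY_LIQUIDS = {1.0: SALINE, 1.88: ICODEXTRIN_4, 2.24: ICODEXTRIN_75}


@dataclass(frozen=True)
class SweepSpec:
    """One study axis, its values, the fixed baseline, and replication."""

    axis: str  # droplet_diameter | flow_rate | viscosity | voltage
    values: tuple = ()
    base: SimulationConfig = field(default_factory=SimulationConfig)
    replicates: int = 5
    seeds: tuple | None = None

    def __post_init__(self):
        if self.axis not in DEFAULT_SWEEP_GRIDS:
            raise ValueError(f"unknown sweep axis {self.axis!r}")
        values = tuple(self.values) if self.values else tuple(
            DEFAULT_SWEEP_GRIDS[self.axis]
        )
        object.__setattr__(self, "values", values)
        if not values:
            raise ValueError("sweep values must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        seeds = self.seeds
        if seeds is None:
            seeds = tuple(self.base.seed + i for i in range(self.replicates))
        seeds = tuple(seeds)
        if len(seeds) != self.replicates:
            raise ValueError("need exactly one seed per replicate")
        object.__setattr__(self, "seeds", seeds)

    def config_for(self, value: float, seed: int) -> SimulationConfig:
        if self.axis == "droplet_diameter":
            cfg = self.base.replace(
                droplet_spec=DropletSizeSpec.monodisperse(value)
            )
        elif self.axis == "flow_rate":
            cfg = self.base.replace(flow_rate=value)
        elif self.axis == "viscosity":
            liquid = _VISCOSITY_LIQUIDS.get(value)
            if liquid is None:
                # interpolate a plausible solution density for the viscosity
                density = 1005.0 + (value - 1.0) / (2.24 - 1.0) * 23.0
                liquid = LiquidProperties(
                    f"custom (mu={value} mPa s)", density, value
                )
            cfg = self.base.replace(liquid=liquid)
        else:  # voltage
            cfg = self.base.replace(voltage=value)
        return cfg.replace(seed=seed)


def run_single(
    config: SimulationConfig,
    geometry: CavityGeometry | None = None,
    gas: GasProperties | None = None,
    field_grid: PotentialGrid | None = None,
) -> tuple[TransportRecords, DepositionReport]:
    """Simulate one configuration and summarize it."""
    geometry = geometry or CavityGeometry()
    records = simulate(config, geometry=geometry, gas=gas, field_grid=field_grid)
    return records, build_report(records, geometry)


def _report_row(axis, value, seed, config, report: DepositionReport) -> dict:
    row = {
        "axis": axis,
        "value": value,
        "seed": seed,
        "n_parcels": config.n_parcels,
    }
    for i, frac in enumerate(report.region_pct, start=1):
        row[f"region{i}_pct"] = frac
    row["airborne_pct"] = report.airborne_pct
    for label, pct in sorted(report.plate_pct.items()):
        row[f"plate_{label}_pct"] = pct
    row["homogeneity"] = report.homogeneity
    row["peak_phi"] = report.peak_phi
    return row


def _config_key(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:16]


def run_sweep(
    spec: SweepSpec,
    geometry: CavityGeometry | None = None,
    gas: GasProperties | None = None,
    cache_dir=None,
) -> pd.DataFrame:
    """Run the sweep; one row per (value, replicate), deterministic per seed.

    The electrostatic Laplace problem is linear in the electrode potential,
    so a voltage sweep solves the field once at a reference potential and
    rescales it.  With ``cache_dir`` set, finished cells are stored keyed by
    a content hash of their configuration, so interrupted sweeps resume.
    """
    geometry = geometry or CavityGeometry()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    reference_grid = None

    def field_for(voltage_kv: float):
        nonlocal reference_grid
        if voltage_kv == 0.0:
            return None
        if reference_grid is None:
            reference_grid = solve_potential(
                geometry, ElectrodeConfig(potential=-1000.0)
            )
        return reference_grid.scaled(abs(voltage_kv))

    rows = []
    for value in spec.values:
        for seed in spec.seeds:
            config = spec.config_for(value, seed)
            key = _config_key(config)
            if cache is not None and (cache / f"{key}.json").exists():
                rows.append(json.loads((cache / f"{key}.json").read_text()))
                continue
            try:
                records = simulate(
                    config,
                    geometry=geometry,
                    gas=gas,
                    field_grid=field_for(config.voltage),
                )
                report = build_report(records, geometry)
            except Exception as exc:
                raise RuntimeError(
                    f"sweep cell failed: axis={spec.axis} value={value} "
                    f"seed={seed}"
                ) from exc
            row = _report_row(spec.axis, value, seed, config, report)
            logger.info(
                "sweep %s=%s seed=%s: regions=%s peak_phi=%.3g",
                spec.axis, value, seed,
                np.round(report.region_pct, 2), report.peak_phi,
            )
            if cache is not None:
                (cache / f"{key}.json").write_text(json.dumps(row))
            rows.append(row)
    return pd.DataFrame(rows)


def reproduce_table1(fixtures: ReferenceFixtures | None = None) -> pd.DataFrame:
    """Recompute the impaction-parameter table d_p^2*Q (integer-truncated).

    Returns one row per case with the recomputed and printed values and a
    ``match`` flag, so any mismatch is visible cell by cell.
    """
    fixtures = fixtures or ReferenceFixtures()
    rows = []
    for case, q, d_um, printed in fixtures.table1:
        computed = int(impaction_parameter(d_um, q))
        rows.append(
            {
                "case": case,
                "flow_rate_mL_per_s": q,
                "diameter_um": d_um,
                "impaction_um2_mL_per_s": computed,
                "printed": printed,
                "match": computed == printed,
            }
        )
    return pd.DataFrame(rows)


def generate_fixture_ensemble(
    seed: int, n: int, config: SimulationConfig | None = None
) -> dict:
    """Reproducible injection ensemble plus analytically expected summaries.

    Intended for pipeline tests: the returned dict carries the sampled
    schedule together with the statistics the sampler should satisfy
    (emission window, volume-median diameter, cone half-angle).
    """
    if n < 100:
        raise ValueError("fixture ensembles need n >= 100")
    config = config or SimulationConfig()
    geometry = CavityGeometry()
    schedule = sample_injection(config, n_parcels=n, seed=seed, geometry=geometry)
    d = schedule.diameters
    order = np.argsort(d)
    cum_vol = np.cumsum(d[order] ** 3)
    vmd = d[order][np.searchsorted(cum_vol, cum_vol[-1] / 2.0)] * 1e6
    axis = geometry.nozzle_direction
    cosines = (schedule.velocities / np.linalg.norm(
        schedule.velocities, axis=1, keepdims=True)) @ axis
    return {
        "schedule": schedule,
        "expected": {
            "emission_window_s": config.injection_duration,
            "volume_median_um": config.droplet_spec.median,
            "mean_diameter_um": float(d.mean() * 1e6),
        },
        "empirical": {
            "max_emission_time_s": float(schedule.emission_times.max()),
            "volume_median_um": float(vmd),
            "min_axis_cosine": float(cosines.min()),
            "mean_lateral": [
                float(np.mean(schedule.velocities[:, 0])),
                float(np.mean(schedule.velocities[:, 1])),
            ],
        },
    }


def export_results(
    results: pd.DataFrame, destination, plots: bool = False
) -> list:
    """Write sweep results as CSV + nested JSON (+ optional bar chart PNG)."""
    if results is None or len(results) == 0:
        raise ValueError("no results to export")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = dest / "sweep_results.csv"
    results.to_csv(csv_path, index=False)
    written.append(csv_path)
    nested = {}
    for (axis, value), group in results.groupby(["axis", "value"]):
        nested.setdefault(str(axis), {})[str(value)] = group.drop(
            columns=["axis", "value"]
        ).to_dict(orient="records")
    json_path = dest / "sweep_results.json"
    json_path.write_text(json.dumps(nested, indent=2))
    written.append(json_path)
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        region_cols = [c for c in results.columns if c.startswith("region")]
        means = results.groupby("value")[region_cols].mean()
        ax = means.plot.bar(figsize=(8, 4))
        ax.set_xlabel(results["axis"].iloc[0])
        ax.set_ylabel("deposition [%]")
        fig_path = dest / "region_fractions.png"
        ax.figure.tight_layout()
        ax.figure.savefig(fig_path, dpi=120)
        plt.close(ax.figure)
        written.append(fig_path)
    return written
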