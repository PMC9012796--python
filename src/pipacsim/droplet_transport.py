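"""Lagrangian droplet transport: forces, dimensionless numbers, integration.

Each aerosol droplet obeys Newton's second law under Stokes drag toward the
local gas velocity, gravity, and (for ePIPAC) the electrostatic force qE:

    m_p du_p/dt = m_p (u - u_p)/tau_p + m_p g + q E,   tau_p = rho_p d_p^2/(18 mu)

With u and E frozen over a step this linear ODE has the exact solution

    u_p(t+dt) = u_inf + (u_p - u_inf) exp(-dt/tau_p),
    u_inf     = u + tau_p (g + q E / m_p),

and the position integrates in closed form.  The integrator below uses this
exponential update, which is unconditionally stable and exact for constant
forcing -- essential because tau_p for 1 um droplets (~4e-6 s) makes the ODE
very stiff at any practical time step.  Step sizes adapt so that no droplet
moves more than a set displacement per step (the only integration error is
the spatial variation of u and E across a step); wall contact is resolved by
bisection on the final step.

A droplet adheres to a surface when the distance from its centre to the wall
falls below its diameter (the wall-adhesion rule of the underlying model,
implemented literally); deposited droplets never move again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core_model import (
    GRAVITY,
    WALL_IDS,
    CavityGeometry,
    GasProperties,
    SimulationConfig,
)
from .gas_flow import FlowFieldModel, coupling_regime, velocity_at, volume_fraction
from .nebulizer import InjectionSchedule, initial_speed, sample_injection

__all__ = [
    "DropletState",
    "TransportRecords",
    "relaxation_time",
    "drag_force",
    "gravitational_force",
    "particle_reynolds",
    "particle_reynolds_as_printed",
    "stokes_number",
    "weber_number",
    "step",
    "detect_deposition",
    "simulate",
    "NOZZLE_TIP_OFFSET",
]

#: The nebulizer tip protrudes this far into the cavity along the nozzle axis.
NOZZLE_TIP_OFFSET = 0.005  # m


# ---------------------------------------------------------------------------
# forces and dimensionless numbers
# ---------------------------------------------------------------------------


def relaxation_time(density: float, diameter, mu: float):
    """Stokes relaxation time tau_p = rho_p d_p^2 / (18 mu) [s]."""
    d = np.asarray(diameter, dtype=float)
    if density <= 0 or mu <= 0 or np.any(d <= 0):
        raise ValueError("density, diameter and viscosity must be positive")
    out = density * d**2 / (18.0 * mu)
    return float(out) if out.ndim == 0 else out


def drag_force(mu: float, diameter: float, u_rel: np.ndarray) -> np.ndarray:
    """Stokes drag F_D = 3 pi mu d_p (u - u_p) [N]."""
    if mu <= 0 or diameter <= 0:
        raise ValueError("viscosity and diameter must be positive")
    return 3.0 * math.pi * mu * diameter * np.asarray(u_rel, dtype=float)


def gravitational_force(density: float, diameter: float) -> np.ndarray:
    """Weight F_G = m_p g along -z [N]."""
    if density <= 0 or diameter < 0:
        raise ValueError("density must be positive, diameter non-negative")
    mass = density * math.pi / 6.0 * diameter**3
    return np.array([0.0, 0.0, -mass * GRAVITY])


def particle_reynolds(gas: GasProperties, u_rel: float, diameter: float) -> float:
    """Particle Reynolds number rho_gas |u - u_p| d_p / mu (standard form)."""
    return gas.density * abs(u_rel) * diameter / gas.dynamic_viscosity


def particle_reynolds_as_printed(
    density_p: float, u_rel: float, mu: float
) -> float:
    """The droplet-density form rho_p |u - u_p| / mu, kept for reference.

    Note this form carries units of 1/length; the standard
    :func:`particle_reynolds` is the default everywhere in the package.
    """
    return density_p * abs(u_rel) / mu


def stokes_number(tau_p: float, u_rel0: float, orifice_diameter: float) -> float:
    """Stk = tau_p |u - u_0p| / (0.5 d_N): ballistic vs. flow response."""
    if orifice_diameter <= 0:
        raise ValueError("orifice diameter must be positive")
    return tau_p * abs(u_rel0) / (0.5 * orifice_diameter)


def weber_number(
    density_p: float, u_rel: float, diameter: float, surface_tension: float
) -> float:
    """We = rho_p |u - u_p|^2 d_p / sigma (breakup diagnostic only)."""
    if surface_tension <= 0:
        raise ValueError("surface tension must be positive")
    return density_p * u_rel**2 * diameter / surface_tension


# ---------------------------------------------------------------------------
# droplet state and single-droplet operations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DropletState:
    """State of one droplet (SI units throughout)."""

    position: np.ndarray
    velocity: np.ndarray
    diameter: float
    density: float
    charge: float = 0.0
    status: str = "airborne"  # "airborne" | "deposited"
    deposit_surface: Optional[str] = None
    deposit_time: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, dtype=float))

    @property
    def mass(self) -> float:
        """m_p = rho_p pi d_p^3 / 6 [kg]."""
        return self.density * math.pi / 6.0 * self.diameter**3


def _exponential_update(pos, vel, u_inf, tau, dt):
    """Closed-form advance of velocity and position over dt (frozen forcing)."""
    exp_f = np.exp(-dt / tau)
    dv = vel - u_inf
    new_vel = u_inf + dv * exp_f[..., None]
    new_pos = pos + u_inf * dt[..., None] + dv * (tau * (1.0 - exp_f))[..., None]
    return new_pos, new_vel


def step(
    state: DropletState,
    gas_velocity: np.ndarray,
    E: np.ndarray,
    dt: float,
    gas: GasProperties | None = None,
) -> DropletState:
    """Advance one droplet by dt with u and E held frozen (exact update)."""
    if state.status != "airborne":
        raise ValueError("cannot step a deposited droplet")
    if dt <= 0:
        raise ValueError("dt must be positive")
    gas = gas or GasProperties()
    tau = relaxation_time(state.density, state.diameter, gas.dynamic_viscosity)
    g_vec = np.array([0.0, 0.0, -GRAVITY])
    u_inf = (
        np.asarray(gas_velocity, dtype=float)
        + tau * (g_vec + state.charge * np.asarray(E, dtype=float) / state.mass)
    )
    new_pos, new_vel = _exponential_update(
        state.position[None, :],
        state.velocity[None, :],
        u_inf[None, :],
        np.array([tau]),
        np.array([dt]),
    )
    return replace(state, position=new_pos[0], velocity=new_vel[0])


def detect_deposition(state: DropletState, geometry: CavityGeometry) -> DropletState:
    """Apply the wall-adhesion rule: deposit iff wall distance < diameter."""
    if state.status != "airborne":
        raise ValueError("droplet already deposited")
    dists = geometry.wall_distances(state.position[None, :])[0]
    if dists.min() < state.diameter:
        wall = WALL_IDS[int(dists.argmin())]
        return replace(state, status="deposited", deposit_surface=wall)
    return state


# ---------------------------------------------------------------------------
# ensemble simulation
# ---------------------------------------------------------------------------


@dataclass
class TransportRecords:
    """Terminal record of every injected droplet of a run."""

    emission_times: np.ndarray
    diameters: np.ndarray
    density: float
    charge: float
    final_positions: np.ndarray  # (n, 3)
    deposited: np.ndarray  # bool
    surfaces: np.ndarray  # wall id string, "" if airborne
    plate_labels: np.ndarray  # plate label string, "" if none
    flight_times: np.ndarray  # s from emission to deposit (or residence)

    def __len__(self):
        return len(self.diameters)

    @property
    def n_deposited(self) -> int:
        return int(self.deposited.sum())

    @property
    def n_airborne(self) -> int:
        return int((~self.deposited).sum())

    def deposit_positions(self) -> np.ndarray:
        return self.final_positions[self.deposited]

    def peak_volume_fraction(self, geometry: CavityGeometry) -> float:
        """Peak instantaneous airborne volume fraction over the run."""
        vols = np.pi / 6.0 * self.diameters**3
        t_in = self.emission_times
        t_out = self.emission_times + self.flight_times
        events = np.concatenate([t_in, t_out])
        deltas = np.concatenate([vols, -vols])
        order = np.argsort(events, kind="stable")
        airborne = np.cumsum(deltas[order])
        return float(airborne.max(initial=0.0) / geometry.volume)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "emission_time_s": self.emission_times,
                "diameter_m": self.diameters,
                "x_m": self.final_positions[:, 0],
                "y_m": self.final_positions[:, 1],
                "z_m": self.final_positions[:, 2],
                "deposited": self.deposited,
                "surface": self.surfaces,
                "plate": self.plate_labels,
                "flight_time_s": self.flight_times,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _bisect_contact(p0, v0, u_inf, tau, dt, diam, geometry, iters=48):
    """First time s in (0, dt] at which wall distance drops to the diameter.

    All arguments are arrays over the droplets that ended their step inside
    the adhesion zone; returns (s, contact position).
    """
    lo = np.zeros(len(dt))
    hi = dt.copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        pos_mid, _ = _exponential_update(p0, v0, u_inf, tau, mid)
        inside = geometry.wall_distance(pos_mid) - diam < 0.0
        hi = np.where(inside, mid, hi)
        lo = np.where(inside, lo, mid)
    pos_c, _ = _exponential_update(p0, v0, u_inf, tau, hi)
    return hi, pos_c


def simulate(
    config: SimulationConfig,
    geometry: CavityGeometry | None = None,
    gas: GasProperties | None = None,
    flow_model: FlowFieldModel | None = None,
    field_grid=None,
    schedule: InjectionSchedule | None = None,
    max_displacement: float = 0.002,
    seed: int | None = None,
) -> TransportRecords:
    """Track every injected droplet until deposition or the end of the run.

    One-way coupling: droplets never alter the gas or the field, so
    trajectories are independent and are advanced together with per-droplet
    adaptive step sizes (bounded by ``max_displacement`` of travel per step).
    ``field_grid`` is a solved :class:`~pipacsim.electrostatics.PotentialGrid`
    (required when config.voltage != 0 unless it can be solved here).
    """
    geometry = geometry or CavityGeometry()
    gas = gas or GasProperties()
    flow_model = flow_model or FlowFieldModel(config.flow_model)
    if field_grid is None and config.voltage != 0.0:
        from .electrostatics import ElectrodeConfig, solve_potential

        field_grid = solve_potential(
            geometry, ElectrodeConfig(potential=-abs(config.voltage) * 1e3)
        )
    if schedule is None:
        schedule = sample_injection(config, seed=seed, geometry=geometry)

    n = len(schedule)
    if n == 0:
        e = np.empty(0)
        return TransportRecords(
            e, e, config.liquid.density, config.droplet_charge,
            np.empty((0, 3)), np.empty(0, bool),
            np.empty(0, object), np.empty(0, object), e,
        )

    # dilute-regime guard (upper bound: every parcel airborne at once)
    coupling_regime(volume_fraction(schedule.diameters, geometry.volume))

    mu = gas.dynamic_viscosity
    rho_p = config.liquid.density
    diam = schedule.diameters.copy()
    tau = relaxation_time(rho_p, diam, mu)
    mass = rho_p * math.pi / 6.0 * diam**3
    q_over_m = config.droplet_charge / mass
    g_vec = np.array([0.0, 0.0, -GRAVITY])
    u0 = initial_speed(config.flow_rate, config.orifice_diameter)

    tip = geometry.nozzle_position + NOZZLE_TIP_OFFSET * geometry.nozzle_direction
    if not geometry.contains(tip[None, :])[0]:
        raise ValueError("nozzle tip lies outside the cavity")

    pos = np.tile(tip, (n, 1))
    vel = schedule.velocities.copy()
    t = np.zeros(n)  # time since emission
    t_budget = config.total_time - schedule.emission_times
    active = np.ones(n, dtype=bool)
    deposited = np.zeros(n, dtype=bool)
    surf_idx = np.full(n, -1, dtype=int)

    quiescent = flow_model.kind == "quiescent"
    forcing_uniform = quiescent and field_grid is None
    dt_max = 5.0 if forcing_uniform else 1.0
    dt_min = 1e-7

    while active.any():
        ia = np.nonzero(active)[0]
        p = pos[ia]
        v = vel[ia]
        if quiescent:
            u_gas = np.zeros_like(p)
        else:
            u_gas = velocity_at(flow_model, p, geometry, u0)
        accel = np.broadcast_to(g_vec, p.shape).copy()
        if field_grid is not None:
            accel = accel + q_over_m[ia, None] * field_grid.field_at(p)
        u_inf = u_gas + tau[ia, None] * accel

        speed = np.maximum(
            np.linalg.norm(v, axis=1), np.linalg.norm(u_inf, axis=1)
        )
        dt = np.clip(max_displacement / (speed + 1e-12), dt_min, dt_max)
        dt = np.minimum(dt, t_budget[ia] - t[ia])
        dt = np.maximum(dt, dt_min)

        new_p, new_v = _exponential_update(p, v, u_inf, tau[ia], dt)
        hit = geometry.wall_distance(new_p) - diam[ia] < 0.0

        if hit.any():
            ih = np.nonzero(hit)[0]
            s_c, p_c = _bisect_contact(
                p[ih], v[ih], u_inf[ih], tau[ia][ih], dt[ih], diam[ia][ih], geometry
            )
            gi = ia[ih]
            new_p[ih] = p_c
            t[gi] += s_c
            deposited[gi] = True
            surf_idx[gi] = geometry.nearest_wall(p_c)
            active[gi] = False
            if not np.all(geometry.contains(p_c, tol=1e-6)):
                raise RuntimeError(
                    "droplet escaped the domain during contact resolution"
                )

        ok = ~hit
        go = ia[ok]
        pos[go] = new_p[ok]
        vel[go] = new_v[ok]
        t[go] += dt[ok]
        # end of run: still airborne
        done = t[go] >= t_budget[go] - 1e-12
        active[go[done]] = False
        pos[ia] = np.where(hit[:, None], new_p, pos[ia])

    surfaces = np.where(
        deposited, np.array(WALL_IDS + ("",), dtype=object)[surf_idx], ""
    ).astype(object)
    plate_labels = np.full(n, "", dtype=object)
    if deposited.any():
        dep_idx = np.nonzero(deposited)[0]
        dep_pos = pos[dep_idx]
        claimed = np.zeros(len(dep_idx), dtype=bool)
        for plate in geometry.plates:
            covered = plate.covers(dep_pos) & ~claimed
            plate_labels[dep_idx[covered]] = plate.label
            claimed |= covered

    return TransportRecords(
        emission_times=schedule.emission_times.copy(),
        diameters=diam,
        density=rho_p,
        charge=config.droplet_charge,
        final_positions=pos,
        deposited=deposited,
        surfaces=surfaces,
        plate_labels=plate_labels,
        flight_times=t,
    )
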