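"""Continuous-phase (CO2) velocity field models and the dilute-coupling check.

The full insufflation flow field is not solved here; two analytic models
stand in for it.  ``quiescent`` treats the gas as still (the cavity is sealed
and the nebulizer adds negligible gas volume), which is the default for the
parameter studies.  ``round_jet`` superimposes a classical self-similar round
jet issuing from the nozzle: centerline speed decaying as u0*B*d_N/s with a
Gaussian radial profile of half-width b = spreading_rate * s.

Droplet momentum feedback onto the gas is neglected (one-way coupling),
justified when the instantaneous airborne volume fraction phi is below 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import CavityGeometry

__all__ = [
    "FlowFieldModel",
    "velocity_at",
    "volume_fraction",
    "coupling_regime",
    "UnsupportedPhysicsError",
    "ONE_WAY_PHI_THRESHOLD",
]

#: Dilute-regime threshold on the airborne volume fraction.
ONE_WAY_PHI_THRESHOLD = 1e-6


class UnsupportedPhysicsError(RuntimeError):
    """Raised when a run would require physics outside the model's scope."""


@dataclass(frozen=True)
class FlowFieldModel:
    """Analytic gas velocity field: ``quiescent`` or ``round_jet``.

    ``decay_constant`` (B) and ``spreading_rate`` are the standard empirical
    round-jet values; ``virtual_origin`` shifts the jet origin upstream of
    the nozzle tip along the axis.
    """

    kind: str = "quiescent"
    decay_constant: float = 6.0
    spreading_rate: float = 0.1
    virtual_origin: float = 0.0  # m

    def __post_init__(self):
        if self.kind not in ("quiescent", "round_jet"):
            raise ValueError(f"unknown flow model {self.kind!r}")


def velocity_at(
    model: FlowFieldModel,
    points: np.ndarray,
    geometry: CavityGeometry,
    u0: float,
    nozzle_position: np.ndarray | None = None,
    nozzle_direction: np.ndarray | None = None,
) -> np.ndarray:
    """Gas velocity [m/s] at interior points, shape (N, 3).

    Quiescent -> zero everywhere.  Round jet -> self-similar profile along
    the nozzle axis, capped at u0 (potential core) and zero outside the
    cavity.  Reduces to quiescent when u0 = 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(geometry.contains(pts, tol=1e-6)):
        raise ValueError("point outside cavity")
    if model.kind == "quiescent" or u0 == 0.0:
        return np.zeros_like(pts)

    pos = geometry.nozzle_position if nozzle_position is None else nozzle_position
    axis = (
        geometry.nozzle_direction if nozzle_direction is None else nozzle_direction
    )
    axis = axis / np.linalg.norm(axis)
    rel = pts - pos
    s = rel @ axis + model.virtual_origin  # axial distance from virtual origin
    radial_vec = rel - np.outer(rel @ axis, axis)
    r = np.linalg.norm(radial_vec, axis=1)

    d_n = 200e-6  # reference orifice scale for the decay law
    with np.errstate(divide="ignore", invalid="ignore"):
        centerline = np.where(s > 0, u0 * model.decay_constant * d_n / s, 0.0)
    centerline = np.minimum(centerline, u0)
    b = model.spreading_rate * np.maximum(s, 1e-12)
    gauss = np.exp(-0.5 * (r / b) ** 2)
    speed = np.where(s > 0, centerline * gauss, 0.0)
    return speed[:, None] * axis


def volume_fraction(diameters: np.ndarray, cavity_volume: float) -> float:
    """Instantaneous airborne volume fraction phi = sum(v_i) / V."""
    if cavity_volume <= 0:
        raise ValueError("cavity volume must be positive")
    d = np.asarray(diameters, dtype=float)
    return float(np.sum(np.pi / 6.0 * d**3) / cavity_volume)


def coupling_regime(
    phi: float, threshold: float = ONE_WAY_PHI_THRESHOLD
) -> str:
    """Classify the two-phase coupling regime from the volume fraction.

    Returns ``"one_way"`` when phi < threshold.  A two-way regime is outside
    this simulator's scope and raises :class:`UnsupportedPhysicsError`.
    """
    if phi < 0:
        raise ValueError("volume fraction must be >= 0")
    if phi < threshold:
        return "one_way"
    raise UnsupportedPhysicsError(
        f"airborne volume fraction {phi:.3g} >= {threshold:.3g}: two-way "
        "momentum coupling would be required, which this one-way coupled "
        "simulator does not support"
    )
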