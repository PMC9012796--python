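"""Electrostatic field inside the cavity for ePIPAC.

A brush electrode (modelled as a small sphere at fixed potential) and
grounded tissue plates impose Dirichlet conditions; the insulating plexiglass
walls are zero-normal-gradient (Neumann).  The Laplace equation is
discretized with a symmetric finite-volume 7-point stencil on a regular
lattice and solved with conjugate gradients.  The electric field E = -grad V
is obtained by central differences and interpolated trilinearly.

The force on a droplet carrying charge q is F_E = q E.  Space charge, corona
charging dynamics and induced-charge effects are neglected: the field is
electrostatic and acts one-way on the droplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core_model import GRAVITY, CavityGeometry

__all__ = [
    "ElectrodeConfig",
    "PotentialGrid",
    "solve_potential",
    "field_at",
    "electric_force",
    "charge_balancing_gravity",
]


@dataclass(frozen=True)
class ElectrodeConfig:
    """Brush electrode pose/potential plus the grounded surfaces.

    ``potential`` is the signed electrode potential in volts (supply limit
    10 kV magnitude).  ``grounded_walls`` lists whole wall faces held at 0 V
    and ``wall_potentials`` assigns arbitrary fixed potentials to faces
    (unused in the default ePIPAC setup, where only the four return-electrode
    plates are grounded; handy for parallel-plate verification cases, where
    ``brush=False`` removes the sphere entirely).
    """

    position: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0912]))
    radius: float = 0.003  # m
    potential: float = -6500.0  # V
    grounded_walls: tuple[str, ...] = ()
    wall_potentials: tuple = ()  # ((wall_id, volts), ...)
    brush: bool = True

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.radius <= 0:
            raise ValueError("electrode radius must be positive")
        if abs(self.potential) > 10e3:
            raise ValueError("electrode potential magnitude limited to 10 kV")


@dataclass
class PotentialGrid:
    """Discretized potential and derived field over the cavity lattice."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    phi: np.ndarray  # (nx, ny, nz), volts
    E: np.ndarray  # (nx, ny, nz, 3), V/m
    residual: float = 0.0

    def __post_init__(self):
        self._interp = None

    def _build_interpolator(self):
        from scipy.interpolate import RegularGridInterpolator

        self._interp = RegularGridInterpolator(
            (self.x, self.y, self.z), self.E, bounds_error=False, fill_value=None
        )

    def field_at(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of E at interior points, shape (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        eps = 1e-9
        if (
            np.any(pts[:, 0] < self.x[0] - eps)
            or np.any(pts[:, 0] > self.x[-1] + eps)
            or np.any(pts[:, 1] < self.y[0] - eps)
            or np.any(pts[:, 1] > self.y[-1] + eps)
            or np.any(pts[:, 2] < self.z[0] - eps)
            or np.any(pts[:, 2] > self.z[-1] + eps)
        ):
            raise ValueError("point outside potential grid domain")
        if self._interp is None:
            self._build_interpolator()
        return self._interp(pts)

    def scaled(self, factor: float) -> "PotentialGrid":
        """Exploit linearity of the Laplace problem: scale all potentials."""
        return PotentialGrid(
            self.x, self.y, self.z, self.phi * factor, self.E * factor, self.residual
        )

    def to_vtk(self, path) -> None:
        """Write a legacy-VTK rectilinear-grid file for visualization."""
        nx, ny, nz = self.phi.shape
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\npipacsim potential\nASCII\n")
            fh.write("DATASET RECTILINEAR_GRID\n")
            fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
            for name, ax in (("X", self.x), ("Y", self.y), ("Z", self.z)):
                fh.write(f"{name}_COORDINATES {len(ax)} float\n")
                fh.write(" ".join(f"{v:.6g}" for v in ax) + "\n")
            fh.write(f"POINT_DATA {nx * ny * nz}\n")
            fh.write("SCALARS potential float 1\nLOOKUP_TABLE default\n")
            for v in self.phi.ravel(order="F"):
                fh.write(f"{v:.6g}\n")


def _dirichlet_masks(
    geometry: CavityGeometry,
    electrodes: ElectrodeConfig,
    X: np.ndarray,
    Y: np.ndarray,
    Z: np.ndarray,
    spacing: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask and value array of fixed-potential nodes."""
    mask = np.zeros(X.shape, dtype=bool)
    vals = np.zeros(X.shape)

    # electrode sphere
    if electrodes.brush:
        r2 = (
            (X - electrodes.position[0]) ** 2
            + (Y - electrodes.position[1]) ** 2
            + (Z - electrodes.position[2]) ** 2
        )
        emask = r2 <= electrodes.radius**2
        if not emask.any():  # snap to the nearest node so the electrode exists
            emask.flat[np.argmin(r2)] = True
        mask |= emask
        vals[emask] = electrodes.potential

    hx, hy = geometry.half_xy
    h = geometry.height
    faces = {
        "x-": X == X.min(),
        "x+": X == X.max(),
        "y-": Y == Y.min(),
        "y+": Y == Y.max(),
        "bottom": Z == Z.min(),
        "top": Z == Z.max(),
    }
    fixed = [(w, 0.0) for w in electrodes.grounded_walls] + list(
        electrodes.wall_potentials
    )
    for wall, volts in fixed:
        fmask = faces[wall]
        vals[fmask & ~mask] = volts
        mask |= fmask

    tol = float(np.max(spacing)) * 0.75
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    boundary = (
        np.isclose(np.abs(pts[:, 0]), hx)
        | np.isclose(np.abs(pts[:, 1]), hy)
        | np.isclose(pts[:, 2], 0.0)
        | np.isclose(pts[:, 2], h)
    )
    for plate in geometry.plates:
        if not plate.grounded:
            continue
        covered = np.zeros(len(pts), dtype=bool)
        covered[boundary] = plate.covers(pts[boundary], tol=tol)
        pmask = covered.reshape(X.shape)
        vals[pmask & ~mask] = 0.0
        mask |= pmask
    return mask, vals


def solve_potential(
    geometry: CavityGeometry,
    electrodes: ElectrodeConfig,
    resolution: int = 48,
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> PotentialGrid:
    """Solve the Laplace equation over the cavity with Dirichlet electrodes.

    ``resolution`` is the node count per axis (>= 16).  Insulating walls are
    zero-normal-gradient.  Raises RuntimeError with the residual if the CG
    iteration fails to converge.
    """
    if resolution < 16:
        raise ValueError("resolution must be >= 16 nodes per axis")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if electrodes.brush and not geometry.contains(electrodes.position[None, :])[0]:
        raise ValueError("electrode must lie inside the cavity")

    hx, hy = geometry.half_xy
    n = resolution
    x = np.linspace(-hx, hx, n)
    y = np.linspace(-hy, hy, n)
    z = np.linspace(0.0, geometry.height, n)
    spacing = np.array([x[1] - x[0], y[1] - y[0], z[1] - z[0]])
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    dmask, dvals = _dirichlet_masks(geometry, electrodes, X, Y, Z, spacing)

    # Finite-volume weights: boundary cells are half-width along each axis,
    # making the face-flux matrix symmetric under Neumann walls.
    def cell_widths(m, h):
        w = np.full(m, h)
        w[0] = w[-1] = h / 2.0
        return w

    wx = cell_widths(n, spacing[0])
    wy = cell_widths(n, spacing[1])
    wz = cell_widths(n, spacing[2])

    shape = (n, n, n)
    ntot = n**3
    idx = np.arange(ntot).reshape(shape)
    unknown = ~dmask
    umap = -np.ones(ntot, dtype=np.int64)
    umap[unknown.ravel()] = np.arange(unknown.sum())

    rows, cols, data = [], [], []
    diag = np.zeros(ntot)
    rhs = np.zeros(ntot)

    # transverse face areas per axis
    area = [
        np.einsum("j,k->jk", wy, wz),  # faces normal to x
        np.einsum("i,k->ik", wx, wz),  # normal to y
        np.einsum("i,j->ij", wx, wy),  # normal to z
    ]

    for axis in range(3):
        h = spacing[axis]
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, n - 1)
        sl_hi[axis] = slice(1, n)
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        # face coefficient c = A_face / h, identical seen from both sides
        if axis == 0:
            A = area[0][None, :, :]
        elif axis == 1:
            A = area[1][:, None, :]
        else:
            A = area[2][:, :, None]
        c = np.broadcast_to(A / h, shape)[tuple(sl_lo)].ravel()

        for a, b in ((i_lo, i_hi), (i_hi, i_lo)):
            ua = umap[a]
            ub = umap[b]
            act = ua >= 0  # row node is unknown
            nb_unknown = act & (ub >= 0)
            nb_dirich = act & (ub < 0)
            rows.append(ua[nb_unknown])
            cols.append(ub[nb_unknown])
            data.append(-c[nb_unknown])
            # accumulate diagonal and Dirichlet RHS
            np.add.at(diag, a[act], c[act])
            np.add.at(rhs, a[nb_dirich], c[nb_dirich] * dvals.ravel()[b[nb_dirich]])

    nunk = int(unknown.sum())
    if nunk == 0:
        phi = dvals.copy()
    else:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.concatenate(data)
        udiag = diag[unknown.ravel()]
        A = sp.coo_matrix(
            (
                np.concatenate([data, udiag]),
                (
                    np.concatenate([rows, np.arange(nunk)]),
                    np.concatenate([cols, np.arange(nunk)]),
                ),
            ),
            shape=(nunk, nunk),
        ).tocsr()
        b = rhs[unknown.ravel()]
        M = sp.diags(1.0 / udiag)
        sol, info = spla.cg(A, b, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
        res = float(np.linalg.norm(A @ sol - b) / max(np.linalg.norm(b), 1e-300))
        if info != 0:
            raise RuntimeError(
                f"Laplace solve did not converge (info={info}, residual={res:.3g})"
            )
        phi = dvals.copy()
        phi[unknown] = sol

    grads = np.gradient(phi, x, y, z)
    E = -np.stack(grads, axis=-1)
    residual = 0.0 if nunk == 0 else res
    return PotentialGrid(x, y, z, phi, E, residual)


def field_at(grid: PotentialGrid, points: np.ndarray) -> np.ndarray:
    """Electric field [V/m] at interior points via trilinear interpolation."""
    return grid.field_at(points)


def electric_force(q: float, E: np.ndarray) -> np.ndarray:
    """Electrostatic force F_E = q E [N] on a droplet of charge q [C]."""
    return q * np.asarray(E, dtype=float)


def charge_balancing_gravity(
    diameter: float, density: float, field_magnitude: float
) -> float:
    """|q| [C] at which the electric force balances gravity for a droplet."""
    if field_magnitude <= 0:
        raise ValueError("field magnitude must be positive")
    mass = density * np.pi / 6.0 * diameter**3
    return mass * GRAVITY / field_magnitude
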