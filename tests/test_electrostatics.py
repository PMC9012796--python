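import numpy as np
import pytest

from pipacsim import (
    CavityGeometry,
    ElectrodeConfig,
    PotentialGrid,
    charge_balancing_gravity,
    electric_force,
    field_at,
    solve_potential,
)
from pipacsim.core_model import GRAVITY


@pytest.fixture(scope="module")
def bare_box():
    # no grounded plates: boundary conditions fully controlled by the test
    return CavityGeometry(plates=())


class TestLaplaceSolver:
    def test_parallel_plate_uniform_field(self, bare_box):
        v = 1000.0
        grid = solve_potential(
            bare_box,
            ElectrodeConfig(brush=False, wall_potentials=(("x-", 0.0), ("x+", v))),
            resolution=32,
            tol=1e-10,
        )
        exact = v / bare_box.extents[0]
        pts = np.array([[0, 0, 0.076], [0.03, -0.02, 0.05], [-0.05, 0.03, 0.12]])
        E = grid.field_at(pts)
        assert np.allclose(-E[:, 0], exact, rtol=0.01)
        assert np.allclose(E[:, 1:], 0.0, atol=exact * 0.01)

    def test_all_grounded_boundary_gives_zero_potential(self, bare_box):
        grid = solve_potential(
            bare_box,
            ElectrodeConfig(
                brush=False,
                grounded_walls=("x-", "x+", "y-", "y+", "bottom", "top"),
            ),
            resolution=16,
        )
        assert np.allclose(grid.phi, 0.0, atol=1e-12)

    def test_potential_linear_in_voltage(self, bare_box):
        kw = dict(position=(0.02, -0.01, 0.08), radius=0.004,
                  grounded_walls=("bottom",))
        g1 = solve_potential(
            bare_box, ElectrodeConfig(potential=-1000.0, **kw),
            resolution=20, tol=1e-10,
        )
        g2 = solve_potential(
            bare_box, ElectrodeConfig(potential=-2000.0, **kw),
            resolution=20, tol=1e-10,
        )
        assert np.allclose(g2.phi, 2 * g1.phi, atol=1e-5 * 2000)
        assert np.allclose(g2.phi, g1.scaled(2.0).phi, atol=1e-5 * 2000)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_discrete_maximum_principle(self, bare_box, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform([-0.05, -0.04, 0.03], [0.05, 0.04, 0.12])
        v = rng.uniform(-9000, -1000)
        grid = solve_potential(
            bare_box,
            ElectrodeConfig(position=pos, radius=0.005, potential=v,
                            grounded_walls=("bottom", "top")),
            resolution=20,
        )
        assert grid.phi.min() >= v - 1e-6
        assert grid.phi.max() <= 0.0 + 1e-6

    def test_field_stronger_near_brush_than_far_wall(self):
        geometry = CavityGeometry()  # grounded plates A-D present
        grid = solve_potential(geometry, ElectrodeConfig(), resolution=32)
        near = np.linalg.norm(grid.field_at([[0, 0, 0.08]])[0])
        far = np.linalg.norm(grid.field_at([[0.08, 0.05, 0.02]])[0])
        assert near > far

    def test_nonconvergence_reported(self, bare_box):
        with pytest.raises(RuntimeError, match="residual"):
            solve_potential(
                bare_box, ElectrodeConfig(grounded_walls=("bottom",)),
                resolution=24, tol=1e-12, max_iter=2,
            )

    def test_invalid_inputs_rejected(self, bare_box):
        with pytest.raises(ValueError):
            solve_potential(bare_box, ElectrodeConfig(), resolution=8)
        with pytest.raises(ValueError):
            ElectrodeConfig(potential=-20e3)
        with pytest.raises(ValueError):
            solve_potential(
                bare_box, ElectrodeConfig(position=(1.0, 0, 0)), resolution=16
            )


class TestFieldInterpolation:
    @pytest.fixture()
    def synthetic_grid(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0])
        z = np.array([0.0, 1.0])
        E = np.zeros((3, 2, 2, 3))
        E[..., 0] = np.arange(3)[:, None, None]  # Ex varies along x only
        phi = np.zeros((3, 2, 2))
        return PotentialGrid(x, y, z, phi, E)

    def test_node_value_exact(self, synthetic_grid):
        assert np.allclose(
            synthetic_grid.field_at([[1.0, 0.0, 0.0]])[0], [1.0, 0.0, 0.0]
        )

    def test_midpoint_is_mean_of_nodes(self, synthetic_grid):
        assert np.allclose(
            synthetic_grid.field_at([[0.5, 0.0, 0.0]])[0], [0.5, 0.0, 0.0]
        )

    def test_uniform_grid_returns_uniform_vector(self):
        x = y = z = np.array([0.0, 1.0])
        E = np.tile(np.array([3.0, -2.0, 1.0]), (2, 2, 2, 1))
        grid = PotentialGrid(x, y, z, np.zeros((2, 2, 2)), E)
        assert np.allclose(grid.field_at([[0.3, 0.7, 0.2]])[0], [3.0, -2.0, 1.0])

    def test_outside_point_rejected(self, synthetic_grid):
        with pytest.raises(ValueError):
            synthetic_grid.field_at([[5.0, 0.0, 0.0]])


class TestElectricForce:
    def test_zero_charge(self):
        assert np.all(electric_force(0.0, [0, 0, 1e5]) == 0.0)

    def test_direct_product(self):
        F = electric_force(-1.6e-14, np.array([0.0, 0.0, 1e5]))
        assert np.allclose(F, [0.0, 0.0, -1.6e-9])

    def test_sign_flip(self):
        E = np.array([1e4, -2e4, 3e4])
        assert np.allclose(electric_force(-2e-14, E), -electric_force(2e-14, E))

    def test_charge_balancing_gravity(self):
        d, rho, E = 30e-6, 1070.0, 1e5
        q = charge_balancing_gravity(d, rho, E)
        mass = rho * np.pi / 6 * d**3
        assert q * E == pytest.approx(mass * GRAVITY)
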