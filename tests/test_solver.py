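"""Integrator: diffusion accuracy, conservation, insulation, symmetry."""

import numpy as np
import pytest

from mcaspol.models import make_minimal_model, ModelSpec, SpeciesSpec
from mcaspol.solver import (
    FieldState,
    Grid,
    SolverControls,
    build_laplacian,
    conserved_totals,
    insulate,
    integrate,
    remove_insulation,
    run_to_steady_state,
)


def diffusion_only_model(Dm=0.01, Dc=1.0) -> ModelSpec:
    base = make_minimal_model(Dm=Dm, Dc=Dc)

    def zero_rates(c):
        return np.zeros_like(c)

    return ModelSpec("diffusion_only", base.species, base.parameters,
                     zero_rates, base.conservation_groups,
                     jacobian=lambda c: np.zeros((2, 2) + np.shape(c[0])))


class TestGrid:
    def test_spacing_and_volume(self):
        g = Grid((100, 50), (10.0, 5.0), bc="noflux")
        assert g.spacing == (0.1, 0.1)
        assert g.cell_volume == pytest.approx(0.01)

    def test_wall_must_lie_on_interface(self):
        g = Grid((100,), (10.0,))
        assert g.wall_index_at(5.0) == 50
        with pytest.raises(ValueError):
            g.wall_index_at(5.03)

    @pytest.mark.parametrize("bc", ["periodic", "noflux"])
    def test_laplacian_rows_sum_to_zero(self, bc):
        g = Grid((40,), (4.0,), bc=bc, walls=(20,) if bc == "noflux" else (0, 20))
        L = build_laplacian(g)
        assert np.abs(L.sum(axis=1)).max() < 1e-12  # conservative stencil

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            Grid((10,), (1.0,), bc="dirichlet")
        with pytest.raises(ValueError):
            Grid((10,), (1.0,), walls=(11,))


class TestDiffusion:
    def test_gaussian_matches_periodic_heat_kernel(self):
        """Free diffusion of a narrow Gaussian reproduces the closed-form
        heat kernel on the circle (image sums) to 1e-4 RMS."""
        model = diffusion_only_model(Dm=0.01)
        g = Grid((500,), (10.0,), bc="periodic")
        x = g.axis_coordinates()
        u0 = np.exp(-((x - 5.0) ** 2) / (2 * 0.04))
        state0 = FieldState(0.0, np.stack([u0, np.zeros_like(u0)]))
        traj = integrate(model, g, state0, 1.0,
                         SolverControls(max_step=0.01))
        D, t, L = 0.01, 1.0, 10.0
        dxs = x[:, None] - x[None, :]
        kernel = sum(np.exp(-((dxs + L * k) ** 2) / (4 * D * t)) for k in range(-5, 6))
        kernel *= g.spacing[0] / np.sqrt(4 * np.pi * D * t)
        ref = kernel @ u0
        rms = np.sqrt(np.mean((traj.states[-1].fields[0] - ref) ** 2))
        assert rms < 1e-4

    def test_stable_steady_state_is_preserved(self, minimal_model, grid_1d):
        # the substrate-only state is steady AND linearly stable (the
        # nontrivial balanced state is Turing-unstable, so round-off would
        # seed genuine pattern growth there)
        state0 = FieldState(0.0, np.stack([np.zeros(grid_1d.shape),
                                           np.full(grid_1d.shape, 2.5)]))
        traj = integrate(minimal_model, grid_1d, state0, 100.0)
        assert np.abs(traj.states[-1].fields - state0.fields).max() < 1e-10

    def test_mirror_symmetric_initial_conditions_stay_symmetric(self, minimal_model):
        g = Grid((200,), (5.0,), bc="periodic")
        x = g.axis_coordinates()
        u = 1.0 + 0.1 * np.cos(2 * np.pi * (x - x.mean()) / 5.0 * 2)
        v = 2.0 - u
        state0 = FieldState(0.0, np.stack([u, v]))
        traj = integrate(minimal_model, g, state0, 5.0)
        f = traj.states[-1].fields
        assert np.abs(f - f[:, ::-1]).max() < 1e-9

    def test_t_end_must_advance(self, minimal_model, grid_1d):
        state0 = FieldState(1.0, np.ones((2, *grid_1d.shape)))
        with pytest.raises(Exception):
            integrate(minimal_model, grid_1d, state0, 0.5)


class TestConservation:
    def test_totals_of_uniform_state(self, minimal_model):
        g = Grid((100,), (10.0,), bc="noflux")
        state = FieldState(0.0, np.stack([np.zeros(100), np.full(100, 2.0)]))
        totals = conserved_totals(minimal_model, g, state)
        assert totals["total"] == pytest.approx(20.0)

    def test_mechanistic_weighted_totals(self, mechanistic_model):
        g = Grid((10, 10), (2.0, 2.0), bc="noflux")
        fields = np.zeros((mechanistic_model.n_species, 10, 10))
        for s in mechanistic_model.species:
            val = 1.0 if s.compartment == "membrane" else 0.5
            fields[mechanistic_model.index(s.name)] = val
        totals = conserved_totals(mechanistic_model, g,
                                  FieldState(0.0, fields))
        # Cdc42 group: 3 membrane species (w=1) + cytosolic (w=1/eta)
        assert totals["Cdc42"] == pytest.approx(4.0 * (3 * 1.0 + 100 * 0.5))

    def test_drift_below_1e8_with_reactions(self, minimal_model, rng):
        g = Grid((200,), (5.0,), bc="periodic")
        fields = rng.uniform(0.5, 2.0, size=(2, 200))
        traj = integrate(minimal_model, g, FieldState(0.0, fields), 50.0)
        assert traj.conservation_drift <= 1e-8


class TestInsulation:
    def test_insulated_halves_conserve_separately(self, minimal_model, rng):
        g = insulate(Grid((200,), (5.0,), bc="noflux"), [2.5])
        fields = np.stack([np.zeros(200), np.where(np.arange(200) < 100, 1.0, 3.0)])
        state0 = FieldState(0.0, fields)
        traj = integrate(minimal_model, g, state0, 20.0)
        final = traj.states[-1].fields
        vol = g.cell_volume
        for sl, expected in ((slice(0, 100), 1.0 * 100 * vol),
                             (slice(100, 200), 3.0 * 100 * vol)):
            got = final[:, sl].sum() * vol / vol  # total over both species
            assert final[:, sl].sum() * vol == pytest.approx(expected, rel=1e-8)

    def test_wall_row_has_no_cross_coupling(self):
        g = insulate(Grid((10,), (1.0,), bc="noflux"), [0.5])
        L = build_laplacian(g).toarray()
        assert L[4, 5] == 0.0 and L[5, 4] == 0.0

    def test_removing_insulation_restores_operator(self):
        g0 = Grid((50,), (5.0,), bc="periodic")
        g1 = remove_insulation(insulate(g0, [2.5]))
        assert (build_laplacian(g0) - build_laplacian(g1)).nnz == 0

    def test_uniform_halves_relax_to_global_uniform(self):
        model = diffusion_only_model(Dm=0.5, Dc=1.0)
        g = Grid((100,), (2.0,), bc="noflux")
        v = np.where(np.arange(100) < 50, 1.0, 3.0)
        state0 = FieldState(0.0, np.stack([v, v]))
        traj = integrate(model, g, state0, 50.0)
        f = traj.states[-1].fields
        assert np.abs(f - 2.0).max() < 1e-6

    def test_totals_invariant_under_insulation(self, minimal_model, rng):
        g0 = Grid((80,), (4.0,), bc="noflux")
        fields = rng.uniform(0.0, 2.0, size=(2, 80))
        state = FieldState(0.0, fields)
        t0 = conserved_totals(minimal_model, g0, state)
        t1 = conserved_totals(minimal_model, insulate(g0, [2.0]), state)
        assert t0 == pytest.approx(t1)


class TestSteadyStateDriver:
    def test_already_steady_returns_immediately(self, minimal_model, grid_1d):
        state0 = FieldState(0.0, np.ones((2, *grid_1d.shape)))
        state, converged, diag = run_to_steady_state(minimal_model, grid_1d, state0)
        assert converged and state.time == 0.0

    def test_subcritical_perturbation_decays_to_homogeneous(self, minimal_model):
        # total below 2: every wavenumber is linearly stable
        g = Grid((100,), (5.0,), bc="noflux")
        x = g.axis_coordinates()
        u = 0.02 * (1 + np.cos(2 * np.pi * x / 5.0))
        v = 1.0 - u
        ctrl = SolverControls(steady_tol=1e-9, max_time=500.0)
        state, converged, diag = run_to_steady_state(
            minimal_model, g, FieldState(0.0, np.stack([u, v])), ctrl)
        f = state.fields
        assert f[0].max() - f[0].min() < 1e-6
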