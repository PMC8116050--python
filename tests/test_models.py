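"""Model library: kinetics, conservation, steady states, linear stability."""

import numpy as np
import pytest

from mcaspol.models import (
    HomogeneousState,
    ModelValidationError,
    hill,
    hill_derivative,
    homogeneous_steady_state,
    linear_growth_rate,
    linear_stability_eigenvalues,
    make_indirect_model,
    make_mechanistic_model,
    make_minimal_model,
    make_model,
    reaction_jacobian,
)


class TestReactionKinetics:
    @pytest.mark.parametrize(
        "state,expected",
        [((1.0, 1.0), (0.0, 0.0)), ((2.0, 2.0), (6.0, -6.0))],
    )
    def test_minimal_pointwise_rates(self, minimal_model, state, expected):
        rates = minimal_model.reaction(np.array(state))
        assert rates == pytest.approx(expected)

    @pytest.mark.parametrize(
        "state,expected",
        [
            ((1.0, 1.0, 0.0), (-0.01, 0.0, 0.01)),
            ((0.0, 0.0, 1.0), (0.0, 1.0, -1.0)),
        ],
    )
    def test_indirect_pointwise_rates(self, indirect_model, state, expected):
        rates = indirect_model.reaction(np.array(state))
        assert rates == pytest.approx(expected, abs=1e-15)

    def test_mechanistic_exchange_balance(self, mechanistic_model):
        # uniform state with only membrane/cytosol exchange active:
        # k5a*Cdc42D_c = k5b*Cdc42D_m and everything else zero
        m = mechanistic_model
        c = np.zeros(m.n_species)
        c[m.index("Cdc42Dm")] = m.parameters["k5a"]
        c[m.index("Cdc42Dc")] = m.parameters["k5b"]
        assert np.allclose(m.reaction(c), 0.0, atol=1e-14)

    def test_reaction_conservation_random_states(self, all_models, rng):
        """Weighted rate sums vanish at machine precision for 1000 states."""
        for model in all_models:
            c = rng.uniform(0.0, 10.0, size=(model.n_species, 1000))
            rates = model.reaction(c)
            for gname in model.group_names:
                w = model.group_weights(gname)
                total = (w[:, None] * rates).sum(axis=0)
                scale = np.abs(w[:, None] * rates).sum(axis=0).max()
                assert np.abs(total).max() <= 1e-12 * max(scale, 1.0)

    def test_analytic_jacobian_matches_finite_differences(self, all_models, rng):
        for model in all_models:
            state = rng.uniform(0.1, 5.0, size=model.n_species)
            Ja = model.jacobian(state)
            Jn = reaction_jacobian(model, state)
            assert np.allclose(Ja, Jn, rtol=1e-5, atol=1e-6 * np.abs(Jn).max())

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ModelValidationError):
            make_minimal_model(a=0.0)
        with pytest.raises(ModelValidationError):
            make_indirect_model(d=-1.0)
        with pytest.raises(ModelValidationError):
            make_mechanistic_model({"eta": 0.0})
        with pytest.raises(ModelValidationError):
            make_mechanistic_model({"nonsense": 1.0})

    def test_nfb_table_swaps_gap_rate(self, mechanistic_model, nfb_model):
        assert mechanistic_model.parameters["k2b"] == 1.75
        assert nfb_model.parameters["k2b"] == 0.35


class TestHillFunctions:
    def test_saturating_limit(self, nfb_model):
        p = nfb_model.parameters
        assert hill(1e9, p["k8max"], p["k8n"], p["k8h"]) == pytest.approx(0.0063, rel=1e-6)

    def test_monotone_and_bounded(self):
        x = np.linspace(0.0, 50.0, 200)
        for vmax, n, h in ((0.0063, 6, 10), (0.0044, 6, 0.003)):
            y = hill(x, vmax, n, h)
            assert np.all(np.diff(y) >= -1e-15)
            assert np.all(y <= vmax + 1e-15)
            assert np.all(hill_derivative(x, vmax, n, h) >= 0.0)


class TestHomogeneousSteadyStates:
    def test_minimal_roots_at_total_2p5(self, minimal_model):
        states = homogeneous_steady_state(minimal_model, 2.5)
        pairs = sorted((s.concentrations["u"], s.concentrations["v"]) for s in states)
        assert pairs[0] == pytest.approx((0.0, 2.5))
        assert pairs[1] == pytest.approx((0.5, 2.0))
        assert pairs[2] == pytest.approx((2.0, 0.5))

    def test_minimal_roots_satisfy_uv_invariant(self, minimal_model):
        for T in (2.0, 3.0, 7.5):
            for s in homogeneous_steady_state(minimal_model, T):
                u, v = s.concentrations["u"], s.concentrations["v"]
                if u > 0:
                    assert u * v == pytest.approx(1.0, rel=1e-12)  # b/a
                assert u + v == pytest.approx(T, rel=1e-12)

    def test_subcritical_total_returns_only_trivial_root(self, minimal_model):
        states = homogeneous_steady_state(minimal_model, 1.0)
        assert len(states) == 1
        assert states[0].concentrations["u"] == 0.0

    def test_indirect_roots_are_steady(self, indirect_model):
        for s in homogeneous_steady_state(indirect_model, 3.0):
            rates = indirect_model.reaction(s.as_array(indirect_model))
            assert np.abs(rates).max() < 1e-12

    def test_mechanistic_relaxed_state_is_steady(self, mechanistic_model):
        states = homogeneous_steady_state(
            mechanistic_model, {"Cdc42": 500.0, "BemGEF": 1.7})
        y = states[-1].as_array(mechanistic_model)
        assert np.abs(mechanistic_model.reaction(y)).max() < 1e-8 * y.max()

    def test_zero_gef_means_no_activation(self, mechanistic_model):
        states = homogeneous_steady_state(
            mechanistic_model, {"Cdc42": 500.0, "BemGEF": 0.0})
        assert states[-1].concentrations["Cdc42T"] == pytest.approx(0.0, abs=1e-10)


class TestLinearStability:
    def test_eigenvalues_at_zero_wavenumber(self, minimal_model):
        ev = np.sort(np.real(linear_stability_eigenvalues(
            minimal_model, np.array([2.0, 0.5]), 0.0)))
        assert ev == pytest.approx([-3.0, 0.0], abs=1e-9)

    def test_zero_eigenvalue_per_conservation_group(self, mechanistic_model):
        hss = homogeneous_steady_state(mechanistic_model,
                                       {"Cdc42": 500.0, "BemGEF": 1.7})[-1]
        ev = linear_stability_eigenvalues(mechanistic_model, hss, 0.0)
        n_zero = np.sum(np.abs(ev) < 1e-6)
        assert n_zero >= len(mechanistic_model.conservation_groups)

    def test_instability_window_boundary(self, minimal_model):
        """Growth is positive for 0 < q^2 < 96 and negative beyond."""
        hss = np.array([2.0, 0.5])
        assert linear_growth_rate(minimal_model, hss, np.sqrt(50.0)) > 0
        assert linear_growth_rate(minimal_model, hss, np.sqrt(95.0)) > 0
        assert linear_growth_rate(minimal_model, hss, np.sqrt(97.0)) < 0
        # determinant of the dispersion matrix changes sign at q^2 = 96
        for q2 in (95.9, 96.1):
            ev = linear_stability_eigenvalues(minimal_model, hss, np.sqrt(q2))
            sign = np.sign(np.prod(np.real(ev)))
            assert sign == (-1 if q2 < 96 else 1)

    def test_non_steady_state_rejected(self, minimal_model):
        with pytest.raises(ModelValidationError):
            linear_growth_rate(minimal_model, np.array([1.0, 2.0]), 1.0)


def test_factory_dispatch():
    assert make_model("minimal").name == "minimal"
    assert make_model("indirect").n_species == 3
    assert make_model("mechanistic").n_species == 6
    assert make_model("mechanistic_nfb").n_species == 9
    with pytest.raises(ModelValidationError):
        make_model("unknown")


def test_validate_accepts_all_models(all_models):
    for model in all_models:
        model.validate()
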