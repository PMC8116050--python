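"""Assay protocols on the (cheap) dimensionless models.

The expensive mechanistic-model protocol checks live in the acceptance
suite; these tests exercise the protocol machinery itself.
"""

import numpy as np
import pytest

from mcaspol.assays import (
    AssayConfig,
    basal_difference_predictor,
    competition_assay,
    default_grid,
    initial_condition,
    phase_diagram,
    predict_from_delta,
    prepare_single_peak,
    saturation_scan,
    unit_totals,
)
from mcaspol.models import make_indirect_model, make_minimal_model
from mcaspol.solver import Grid, conserved_totals


@pytest.fixture(scope="module")
def small_half_grid():
    return Grid((125,), (2.5,), bc="noflux")


class TestUnitTotals:
    def test_minimal_one_x_is_uniform_substrate_2(self, minimal_model):
        assert unit_totals(minimal_model, 1.0) == {"total": 2.0}
        assert unit_totals(minimal_model, 0.6) == {"total": pytest.approx(1.2)}

    def test_mechanistic_totals_weighted_by_eta(self, mechanistic_model):
        totals = unit_totals(mechanistic_model, 1.0)
        assert totals["Cdc42"] == pytest.approx(500.0)  # 5 uM / eta
        assert totals["BemGEF"] == pytest.approx(1.7)

    def test_per_group_multipliers(self, mechanistic_model):
        totals = unit_totals(mechanistic_model, {"Cdc42": 2.0})
        assert totals["Cdc42"] == pytest.approx(1000.0)
        assert totals["BemGEF"] == pytest.approx(1.7)


class TestInitialCondition:
    def test_exact_totals_after_renormalization(self, minimal_model, small_half_grid):
        state = initial_condition(minimal_model, small_half_grid, 1.3, seed=4)
        totals = conserved_totals(minimal_model, small_half_grid, state)
        area = small_half_grid.cell_volume * small_half_grid.n_cells
        assert totals["total"] == pytest.approx(2.0 * 1.3 * area, rel=1e-12)

    def test_zero_noise_and_no_bump_is_homogeneous(self, minimal_model, small_half_grid):
        from mcaspol.synthetic import noisy_initial_condition
        state = noisy_initial_condition(minimal_model, small_half_grid, 1.0,
                                        amplitude=0.0)
        assert np.ptp(state.fields[1]) == 0.0
        assert state.fields[0].max() == 0.0

    def test_same_seed_is_bit_identical(self, minimal_model, small_half_grid):
        a = initial_condition(minimal_model, small_half_grid, 1.0, seed=9)
        b = initial_condition(minimal_model, small_half_grid, 1.0, seed=9)
        assert np.array_equal(a.fields, b.fields)


class TestPrepareSinglePeak:
    def test_one_peak_with_depressed_basal_substrate(self, minimal_model,
                                                     small_half_grid):
        prep = prepare_single_peak(minimal_model, small_half_grid, 1.0, seed=0)
        assert not prep.no_peak
        assert prep.peaks.n_peaks == 1
        assert prep.basal["v"] < 2.0  # substrate depleted below the uniform start

    def test_determinism(self, minimal_model, small_half_grid):
        a = prepare_single_peak(minimal_model, small_half_grid, 1.0, seed=0)
        b = prepare_single_peak(minimal_model, small_half_grid, 1.0, seed=0)
        assert np.array_equal(a.state.fields, b.state.fields)

    def test_far_subcritical_amount_gives_no_peak(self, minimal_model,
                                                  small_half_grid):
        prep = prepare_single_peak(minimal_model, small_half_grid, 0.01, seed=0)
        assert prep.no_peak

    def test_conserved_total_matches_request(self, minimal_model, small_half_grid):
        prep = prepare_single_peak(minimal_model, small_half_grid, 0.8, seed=0)
        totals = conserved_totals(minimal_model, small_half_grid, prep.state)
        area = small_half_grid.cell_volume * small_half_grid.n_cells
        assert totals["total"] == pytest.approx(1.6 * area, rel=1e-8)


class TestCompetitionAssay:
    def test_amount_additivity_after_wall_removal(self, minimal_model):
        grid = Grid((250,), (5.0,), bc="noflux")
        res = competition_assay(minimal_model, (0.6, 1.0), grid=grid, seed=0)
        # conserved totals equal the sum of the two subsystem shares
        area = grid.cell_volume * grid.n_cells
        expected = 2.0 * (0.6 + 1.0) / 2 * area
        assert res.conservation_drift < 1e-8
        assert res.outcome.label == "competition"
        assert res.meta["amounts"] == (0.6, 1.0)

    def test_trace_fractions_sum_to_one(self, minimal_model):
        grid = Grid((250,), (5.0,), bc="noflux")
        res = competition_assay(minimal_model, (0.6, 1.0), grid=grid, seed=0)
        sums = res.trace.fractions.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_failed_subsystem_raises(self, minimal_model):
        grid = Grid((250,), (5.0,), bc="noflux")
        with pytest.raises(RuntimeError, match="no peak"):
            competition_assay(minimal_model, (0.01, 1.0), grid=grid, seed=0)


class TestSaturationScan:
    def test_minimal_peak_saturates_and_basal_declines(self, minimal_model,
                                                       small_half_grid):
        tab = saturation_scan(minimal_model, (0.6, 1.0, 2.0, 4.0),
                              grid=small_half_grid, seed=0)
        assert not tab["no_peak"].any()
        peak = tab["peak_activator"].to_numpy()
        basal = tab["basal_v"].to_numpy()
        assert np.all(np.diff(peak) > 0)            # amplitude rises...
        assert np.diff(peak)[-1] < np.diff(peak)[0]  # ...with shrinking steps
        assert np.all(np.diff(basal) <= 1e-9)        # basal declines to a limit

    def test_unsorted_multipliers_rejected(self, minimal_model):
        with pytest.raises(ValueError):
            saturation_scan(minimal_model, (1.0, 0.6))

    def test_no_peak_rows_flagged_not_dropped(self, minimal_model, small_half_grid):
        tab = saturation_scan(minimal_model, (0.01, 1.0), grid=small_half_grid)
        assert len(tab) == 2
        assert bool(tab["no_peak"].iloc[0]) and not bool(tab["no_peak"].iloc[1])
        assert np.isnan(tab["peak_activator"].iloc[0])

    def test_indirect_basal_vi_increases_with_amount(self, indirect_model,
                                                     small_half_grid):
        tab = saturation_scan(indirect_model, (0.6, 1.0, 1.8),
                              grid=small_half_grid, seed=0)
        vi = tab["basal_v_i"].to_numpy()
        assert np.all(np.diff(vi) > 0)

    def test_indirect_basal_v_dips_then_rises(self, indirect_model,
                                              small_half_grid):
        tab = saturation_scan(indirect_model, (0.6, 1.0, 1.8),
                              grid=small_half_grid, seed=0)
        v = tab["basal_v"].to_numpy()
        assert v[1] < v[0] and v[2] > v[1]


class TestBasalDifferencePredictor:
    def test_sign_convention(self):
        assert predict_from_delta(0.01) == "equalization"
        assert predict_from_delta(-0.01) == "competition"
        assert predict_from_delta(2e-5) == "coexistence"

    def test_minimal_model_never_predicts_equalization(self, minimal_model):
        dv, label = basal_difference_predictor(minimal_model, (0.4, 0.6), seed=0)
        assert dv <= 0
        assert label in ("competition", "coexistence")

    def test_symmetric_amounts_give_zero_difference(self, minimal_model):
        dv, label = basal_difference_predictor(minimal_model, (0.8, 0.8), seed=0)
        assert dv == pytest.approx(0.0, abs=1e-9)

    def test_indirect_equalizing_pair_has_positive_difference(self, indirect_model):
        dv, label = basal_difference_predictor(indirect_model, (0.8, 1.2), seed=0)
        assert dv > 0
        assert label == "equalization"


class TestPhaseDiagramMachinery:
    def test_tiny_sweep_structure_and_reproducibility(self):
        kwargs = dict(
            Dvi_values=(0.01, 1.0), amount_values=(1.5, 2.0),
            grid=Grid((125,), (5.0,), bc="noflux"), seed=0,
            config=AssayConfig(t_max=400.0),
        )
        pd1 = phase_diagram(**kwargs)
        pd2 = phase_diagram(**kwargs)
        assert pd1.labels.shape == (2, 2)
        assert pd1.delta_v.shape == (2, 2)
        assert (pd1.table["label"] == pd2.table["label"]).all()
        assert np.allclose(pd1.delta_v, pd2.delta_v, equal_nan=True)
        assert set(pd1.table.columns) >= {"Dvi", "amount", "label", "delta_v", "seed"}

    def test_undersized_sweep_rejected(self):
        with pytest.raises(ValueError):
            phase_diagram((1.0,), (1.0, 2.0))


def test_default_grids():
    mini = make_minimal_model()
    assert default_grid(mini).shape == (500,)
    assert default_grid(mini, half=True).lengths == (2.5,)
    from mcaspol.models import make_mechanistic_model
    mech = make_mechanistic_model()
    assert default_grid(mech).shape == (100, 100)
    assert default_grid(mech, resolution=24, half=True).shape == (12, 24)
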