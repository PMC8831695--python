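"""Hill stages, gate composition, and stage-wise fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crispri_circuits.circuit_models import (
    CircuitModel,
    CrispriStage,
    HillStage,
    cascade_predict,
    crispri_not_predict,
    fit_cascade,
    fit_stage,
    hill_eval,
    nor_predict,
)
from crispri_circuits.equilibrium_model import (
    BindingParams,
    SpeciesTotals,
    TransferCurve,
    solve_equilibrium_oracle,
)
from crispri_circuits.synthetic_data import CurveTruth, generate_curve

REP = HillStage(kind="repression", basal=10.0, range=100.0, Km=5.0, n=2.0)
ACT = HillStage(kind="activation", basal=0.0, range=50.0, Km=2.0, n=1.5)


class TestHillEval:
    def test_repression_at_zero_input_is_full_output(self):
        assert hill_eval(REP, 0.0) == pytest.approx(110.0)

    @pytest.mark.parametrize("n", [0.5, 1.0, 2.0, 4.0])
    def test_repression_at_km_is_half_range_for_any_n(self, n):
        stage = HillStage(kind="repression", basal=10.0, range=100.0, Km=5.0, n=n)
        assert hill_eval(stage, 5.0) == pytest.approx(60.0)

    def test_activation_saturates_at_basal_plus_range(self):
        assert hill_eval(ACT, 1e9) == pytest.approx(50.0, rel=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HillStage(kind="repression", basal=-1, range=1, Km=1, n=1)
        with pytest.raises(ValueError):
            HillStage(kind="repression", basal=0, range=1, Km=0, n=1)
        with pytest.raises(ValueError):
            HillStage(kind="sigmoid", basal=0, range=1, Km=1, n=1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(x1=st.floats(0.0, 1e3), x2=st.floats(0.0, 1e3))
    def test_repression_monotone_decreasing_activation_increasing(self, x1, x2):
        lo, hi = sorted((x1, x2))
        assert hill_eval(REP, hi) <= hill_eval(REP, lo)
        assert hill_eval(ACT, hi) >= hill_eval(ACT, lo)


class TestCascade:
    def test_single_stage_equals_hill_eval(self):
        model = CircuitModel(topology="cascade", stages=[REP])
        x = np.geomspace(0.1, 100, 11)
        np.testing.assert_allclose(cascade_predict(model, x), hill_eval(REP, x))

    def test_double_inversion_is_increasing(self):
        ideal = HillStage(kind="repression", basal=0.0, range=100.0, Km=5.0, n=2.0)
        model = CircuitModel(topology="cascade", stages=[ideal, ideal])
        x = np.geomspace(0.01, 1e3, 30)
        y = cascade_predict(model, x)
        assert np.all(np.diff(y) >= -1e-9)

    def test_odd_number_of_inversions_is_decreasing(self):
        ideal = HillStage(kind="repression", basal=0.0, range=100.0, Km=5.0, n=2.0)
        model = CircuitModel(topology="cascade", stages=[ideal] * 3)
        y = cascade_predict(model, np.geomspace(0.01, 1e3, 30))
        assert np.all(np.diff(y) <= 1e-9)

    def test_empty_cascade_is_an_error(self):
        with pytest.raises(ValueError):
            CircuitModel(topology="cascade", stages=[])


class TestCrispriNot:
    @pytest.fixture
    def model(self, params):
        activation = HillStage(kind="activation", basal=0.0, range=1000.0,
                               Km=10.0, n=1.2)
        return CircuitModel(
            topology="cascade",
            crispri_stage=CrispriStage(
                activation=activation,
                params=BindingParams(K1=0.3, K2=2.0, theta=2.0),
                totals=SpeciesTotals(Ctot=100.0, gtot=0.0, Dtot=10.0),
            ),
        )

    def test_no_inducer_no_sgrna_full_output(self, model):
        assert crispri_not_predict(model, 0.0) == pytest.approx(2.0 * 10.0)

    def test_saturating_inducer_represses_fully(self, model):
        assert crispri_not_predict(model, 1e9) < 0.05 * 2.0 * 10.0

    def test_mid_curve_agrees_with_oracle_solve(self, model):
        inducer = 10.0
        gtot = hill_eval(model.crispri_stage.activation, inducer)
        expected = solve_equilibrium_oracle(
            model.crispri_stage.params,
            SpeciesTotals(Ctot=100.0, gtot=gtot, Dtot=10.0),
        ).R
        assert crispri_not_predict(model, inducer) == pytest.approx(
            expected, rel=1e-6
        )

    def test_missing_crispri_stage_is_an_error(self):
        model = CircuitModel(topology="cascade", stages=[REP])
        with pytest.raises(ValueError):
            crispri_not_predict(model, 1.0)


class TestNor:
    @pytest.fixture
    def model(self):
        s1 = HillStage(kind="repression", basal=0.0, range=1.0, Km=5.0, n=2.0)
        s2 = HillStage(kind="repression", basal=0.0, range=1.0, Km=50.0, n=1.5)
        return CircuitModel(topology="nor", stages=[s1, s2], basal=3.0, range=90.0)

    def test_both_inputs_low_gives_high_output(self, model):
        assert nor_predict(model, 0.0, 0.0) == pytest.approx(93.0)

    @pytest.mark.parametrize("a,b", [(1e9, 0.0), (0.0, 1e9), (1e9, 1e9)])
    def test_any_high_input_drops_to_basal(self, model, a, b):
        assert nor_predict(model, a, b) == pytest.approx(3.0, rel=1e-3)

    def test_swapping_stages_and_inputs_is_symmetric(self, model):
        swapped = CircuitModel(
            topology="nor", stages=[model.stages[1], model.stages[0]],
            basal=model.basal, range=model.range,
        )
        for a, b in [(1.0, 30.0), (7.0, 7.0), (0.0, 100.0)]:
            assert nor_predict(model, a, b) == pytest.approx(
                nor_predict(swapped, b, a)
            )

    def test_non_nor_model_is_rejected(self):
        model = CircuitModel(topology="cascade", stages=[REP])
        with pytest.raises(ValueError):
            nor_predict(model, 1.0, 1.0)
        with pytest.raises(ValueError):
            CircuitModel(topology="nor", stages=[REP])


class TestFitStage:
    def test_noise_free_repression_recovered_exactly(self):
        grid = np.geomspace(0.1, 500.0, 8)
        curve = TransferCurve("inducer", grid, "output", hill_eval(REP, grid))
        res = fit_stage(curve, "repression")
        assert res.estimates["basal"] == pytest.approx(10.0, abs=1e-4)
        assert res.estimates["range"] == pytest.approx(100.0, rel=1e-5)
        assert res.estimates["Km"] == pytest.approx(5.0, rel=1e-5)
        assert res.estimates["n"] == pytest.approx(2.0, rel=1e-5)
        assert res.residual_norm < 1e-12

    def test_noisy_replicates_recover_km_and_n(self):
        truth = CurveTruth(generator="hill", hill_stage=REP, noise_cv=0.10,
                           replicates=3, seed=42)
        grid = np.geomspace(0.1, 500.0, 8)
        data, clean, _ = generate_curve(truth, grid)
        wide = data.pivot_table(index="input_value", columns="replicate",
                                values="output_value").sort_index()
        curve = TransferCurve("inducer", wide.index.to_numpy(), "output",
                              wide[1].to_numpy())
        res = fit_stage(curve, "repression",
                        replicate_outputs=[wide[2].to_numpy(), wide[3].to_numpy()])
        assert res.estimates["Km"] == pytest.approx(5.0, rel=0.25)
        assert res.estimates["n"] == pytest.approx(2.0, rel=0.35)

    def test_underdetermined_data_is_an_error(self):
        grid = np.array([0.1, 1.0, 10.0])
        curve = TransferCurve("x", grid, "y", hill_eval(REP, grid))
        with pytest.raises(ValueError):
            fit_stage(curve, "repression")

    def test_all_zero_outputs_is_an_error(self):
        grid = np.geomspace(0.1, 100, 6)
        curve = TransferCurve("x", grid, "y", np.zeros_like(grid))
        with pytest.raises(ValueError):
            fit_stage(curve, "repression")


class TestFitCascade:
    def test_single_stage_topology_equals_fit_stage(self):
        grid = np.geomspace(0.1, 500.0, 10)
        curve = TransferCurve("x", grid, "y", hill_eval(REP, grid))
        model = fit_cascade([curve], ["repression"])
        direct = fit_stage(curve, "repression").stage
        assert model.stages[0] == direct

    def test_two_stage_fit_composes_to_end_to_end_truth(self):
        s2 = HillStage(kind="repression", basal=2.0, range=80.0, Km=40.0, n=1.5)
        grid1 = np.geomspace(0.1, 500.0, 12)
        curve1 = TransferCurve("x", grid1, "y", hill_eval(REP, grid1))
        grid2 = np.geomspace(1.0, 200.0, 12)
        curve2 = TransferCurve("x", grid2, "y", hill_eval(s2, grid2))
        model = fit_cascade([curve1, curve2], ["repression", "repression"])
        x = np.geomspace(0.5, 200.0, 15)
        truth = hill_eval(s2, hill_eval(REP, x))
        np.testing.assert_allclose(cascade_predict(model, x), truth, rtol=1e-3)

    def test_nor_topology_builds_nor_model(self):
        grid = np.geomspace(0.1, 500.0, 8)
        c1 = TransferCurve("x", grid, "y", hill_eval(REP, grid))
        c2 = TransferCurve("x", grid, "y", hill_eval(REP, grid))
        model = fit_cascade([c1, c2], "nor")
        assert model.topology == "nor"
        assert len(model.stages) == 2

    def test_dataset_count_mismatch_is_an_error(self):
        grid = np.geomspace(0.1, 500.0, 8)
        c1 = TransferCurve("x", grid, "y", hill_eval(REP, grid))
        with pytest.raises(ValueError):
            fit_cascade([c1], ["repression", "repression"])


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        model = CircuitModel(
            topology="nor",
            stages=[REP, HillStage(kind="repression", basal=0, range=1,
                                   Km=50.0, n=1.5)],
            basal=3.0, range=90.0,
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = CircuitModel.from_json(path)
        assert loaded == model
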