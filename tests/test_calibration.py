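"""Loss function, goodness-of-fit metrics and the fitting machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirodeb import ForcingScenario, chironomus_riparius
from chirodeb.calibration import (
    FitSpecification,
    evaluate,
    fit_parameters,
    goodness_of_fit,
    symmetric_bounded_loss,
)
from chirodeb.datasets import CalibrationDataset, generate_synthetic_datasets
from chirodeb.model import DEBLifeCycleModel


class TestSymmetricBoundedLoss:
    def test_exact_predictions_give_zero(self):
        assert symmetric_bounded_loss([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_computed_contribution(self):
        # (1-3)^2 / (1^2+3^2) = 4/10
        assert symmetric_bounded_loss([1.0], [3.0]) == pytest.approx(0.4)

    def test_scale_invariance_and_symmetry(self):
        base = symmetric_bounded_loss([1.0], [3.0])
        for c in (0.01, 7.0, 1e4):
            assert symmetric_bounded_loss([c], [3 * c]) == pytest.approx(base)
        assert symmetric_bounded_loss([3.0], [1.0]) == pytest.approx(base)

    def test_zero_zero_defined_as_zero(self):
        assert symmetric_bounded_loss([0.0], [0.0]) == 0.0

    @given(d=st.floats(0.0, 1e6), p=st.floats(0.0, 1e6), w=st.floats(0.0, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_weight(self, d, p, w):
        assert 0.0 <= symmetric_bounded_loss([d], [p], [w]) <= w + 1e-12

    def test_rejects_negative_weights_and_shape_mismatch(self):
        with pytest.raises(ValueError):
            symmetric_bounded_loss([1.0], [1.0], [-1.0])
        with pytest.raises(ValueError):
            symmetric_bounded_loss([1.0, 2.0], [1.0])


def _toy_dataset(name, y, weight=1.0, observable="age_at_pupation"):
    return CalibrationDataset(
        name=name, kind="zero_variate", observable=observable,
        scenario=ForcingScenario(), data=pd.DataFrame({"x": [0.0], "y": [y]}),
        weight=weight,
    )


class TestGoodnessOfFit:
    def test_exact_fit_identities(self):
        ds = [_toy_dataset("a", 10.0)]
        rep = goodness_of_fit(ds, [np.array([10.0])])
        assert rep.MRE == 0.0 and rep.SMSE == 0.0 and rep.loss_value == 0.0

    def test_single_point_relative_error(self):
        rep = goodness_of_fit([_toy_dataset("a", 10.0)], [np.array([11.0])])
        assert rep.MRE == pytest.approx(0.1)

    def test_zero_datum_excluded_from_mre(self):
        ds = CalibrationDataset(
            name="z", kind="uni_variate", observable="length",
            scenario=ForcingScenario(),
            data=pd.DataFrame({"x": [1.0, 2.0], "y": [0.0, 2.0]}))
        rep = goodness_of_fit([ds], [np.array([0.5, 2.2])])
        assert rep.MRE == pytest.approx(0.1)  # only the nonzero datum counts

    def test_dataset_order_invariance(self):
        ds = [_toy_dataset("a", 10.0), _toy_dataset("b", 5.0, weight=2.0)]
        preds = [np.array([12.0]), np.array([4.0])]
        fwd = goodness_of_fit(ds, preds)
        rev = goodness_of_fit(ds[::-1], preds[::-1])
        assert fwd.loss_value == pytest.approx(rev.loss_value)
        assert fwd.MRE == pytest.approx(rev.MRE)

    def test_smse_bounded_unit_interval(self):
        rep = goodness_of_fit([_toy_dataset("a", 10.0)], [np.array([1e6])])
        assert 0.0 <= rep.SMSE <= 1.0


class TestFitting:
    def test_zero_free_parameters_returns_initial(self, params):
        ds = [_toy_dataset("a", 14.0)]
        out = fit_parameters(params, ds, FitSpecification(free=()))
        assert out.params == params
        assert out.converged

    def test_pseudo_datum_pulls_maintenance_ratio(self):
        """With only the k = 1 pseudo-datum, a mis-specified kJ moves toward
        [pM]/[EG] (where the maintenance ratio is 1)."""
        start = chironomus_riparius().replace(kJ=0.010)
        spec = FitSpecification(free=("kJ",), restarts=1, maxiter=200)
        out = fit_parameters(start, [], spec)
        target = start.pM / start.EG
        assert abs(out.params.kJ - target) < 0.1 * abs(start.kJ - target)

    def test_pseudo_data_vanish_with_weight(self, params):
        from chirodeb.calibration import _total_loss
        from chirodeb.parameters import CompositionParams

        start = params.replace(kJ=0.010)
        spec0 = FitSpecification(free=("kJ",),
                                 pseudo_data={"maintenance_ratio": (1.0, 0.0)})
        assert _total_loss(start, [], spec0, CompositionParams()) == 0.0

    def test_noiseless_recovery_reaches_tiny_loss(self, params, scenario21):
        """With truth in the search space and exact data, the optimizer
        drives the loss below 1e-6 from a small perturbation."""
        ds = generate_synthetic_datasets(
            params, scenario21, times=[3.0, 8.0, 12.0], cv=0.0, seed=0,
            observables=("length",), events=("age_at_pupation",))
        start = params.replace(pAm=params.pAm * 1.05)
        spec = FitSpecification(free=("pAm",), restarts=1, maxiter=60,
                                pseudo_data={})
        out = fit_parameters(start, ds, spec)
        assert out.loss_report.loss_value < 1e-6
        assert out.params.pAm == pytest.approx(params.pAm, rel=1e-3)

    def test_history_logs_improvements(self, params, scenario21):
        ds = generate_synthetic_datasets(
            params, scenario21, times=[5.0], cv=0.0, seed=0,
            observables=("length",), events=())
        start = params.replace(v=params.v * 1.1)
        out = fit_parameters(start, ds,
                             FitSpecification(free=("v",), restarts=1, maxiter=30,
                                              pseudo_data={}))
        assert len(out.history) >= 1
        assert (np.diff(out.history.loss) <= 0).all()


class TestModelObjects:
    def test_prediction_only_mode(self, params):
        from chirodeb.datasets import packaged_zero_variate_data

        model = DEBLifeCycleModel(packaged_zero_variate_data(), params=params)
        res = model.fit()  # no free parameters: evaluate the starting set
        assert res.params == params
        assert res.loss > 0
        assert "MRE" in res.summary()
        table = res.loss_report.per_dataset
        assert len(table) == 13

    def test_from_tables_roundtrip(self, params, scenario21):
        tables = {
            "growth": pd.DataFrame({"x": [2.0, 6.0], "y": [0.3, 0.8]}),
            "pupation": pd.DataFrame({"x": [0.0], "y": [14.0]}),
        }
        model = DEBLifeCycleModel.from_tables(
            tables, scenario21,
            observables={"growth": "length", "pupation": "age_at_pupation"},
            params=params)
        assert {ds.kind for ds in model.datasets} == {"uni_variate", "zero_variate"}
        preds = model.predict()
        assert preds["growth"].shape == (2,)

    def test_loss_matches_evaluate(self, params):
        ds = [_toy_dataset("a", 14.0)]
        model = DEBLifeCycleModel(ds, params=params)
        assert model.loss().loss_value == pytest.approx(
            evaluate(params, ds).loss_value)
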