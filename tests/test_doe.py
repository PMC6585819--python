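import math

import numpy as np
import pytest

from gridsimplex.desirability import DesirabilityTable, WeightVector
from gridsimplex.doe import (
    PROFILES,
    QuarticModel,
    assess_doe,
    doe_baseline_assessment,
    fit_response,
    quartic_term_pool,
    select_model,
    stepwise_fit,
)
from gridsimplex.grid import MeasurementTable, ResponseDef, build_grid, code_levels
from gridsimplex.weights import WeightGrid, enumerate_weight_sets


class TestTermPool:
    @pytest.mark.parametrize("n,expected", [(1, 5), (2, 15), (3, 35)])
    def test_pool_size_is_stars_and_bars_count(self, n, expected):
        pool = quartic_term_pool(n)
        assert len(pool) == expected
        assert pool[0] == (0,) * n
        assert all(sum(t) <= 4 for t in pool)
        assert len(set(pool)) == len(pool)


class TestStepwiseFit:
    def test_noiseless_quadratic_recovered_exactly(self, case_grid):
        conds = case_grid.conditions
        y = [3.0 + 2.0 * c[0] ** 2 for c in conds]
        model = stepwise_fit(conds, y)
        assert model.rmse == pytest.approx(0.0, abs=1e-8)
        preds = model.predict(conds)
        assert np.allclose(preds, y, atol=1e-8)
        # the x1^2 effect is captured by terms in x1 only
        assert any(t[0] > 0 for t in model.terms[1:])
        assert all(t[1] == 0 and t[2] == 0 for t in model.terms[1:])

    def test_constant_response_gives_intercept_only(self, case_grid):
        conds = case_grid.conditions
        model = stepwise_fit(conds, [7.5] * len(conds))
        assert model.terms == ((0, 0, 0),)
        assert model.coef[0] == pytest.approx(7.5)

    def test_pure_noise_admits_few_terms(self, case_grid):
        conds = case_grid.conditions
        admitted = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            model = stepwise_fit(conds, rng.normal(size=len(conds)))
            admitted.append(model.n_terms - 1)
        # at p_enter = 0.05 false entries are rare; allow selection bias slack
        assert sum(admitted) <= 15
        assert min(admitted) <= 2

    def test_never_worse_than_intercept_only(self, case_grid):
        conds = case_grid.conditions
        rng = np.random.default_rng(1)
        y = np.asarray([c[0] + 0.2 * c[2] for c in conds]) + rng.normal(
            0, 0.5, len(conds)
        )
        model = stepwise_fit(conds, y)
        intercept_rmse = float(np.std(y))
        assert model.rmse <= intercept_rmse + 1e-12


class TestSelectModel:
    def _model(self, rmse, n_extra):
        terms = tuple([(0,)] + [(d,) for d in range(1, n_extra + 1)])
        return QuarticModel(
            terms=terms, coef=(0.0,) * len(terms), center=(0.0,), rmse=rmse
        )

    def test_lowest_rmse_wins(self):
        models = [self._model(0.9, 1), self._model(0.4, 2), self._model(0.7, 1)]
        assert select_model(models) is models[1]

    def test_single_candidate(self):
        m = self._model(1.0, 1)
        assert select_model([m]) is m

    def test_tie_goes_to_fewer_terms(self):
        m5 = self._model(0.4, 4)
        m3 = self._model(0.4, 2)
        assert select_model([m5, m3]) is m3

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_model([])


def _dtable(grid, values, w=(1.0, 1.0, 1.0)):
    return DesirabilityTable(weights=WeightVector(w=w), values=values)


class TestAssessDoe:
    @pytest.fixture()
    def small_grid(self):
        return build_grid([code_levels([1, 2, 3]), code_levels([1, 2, 3])])

    def test_identical_tables_pass_both_profiles(self, small_grid):
        rng = np.random.default_rng(0)
        vals = {c: float(v) for c, v in zip(
            small_grid.conditions, rng.uniform(0.1, 0.9, 9))}
        measured = [_dtable(small_grid, vals)]
        predicted = [_dtable(small_grid, dict(vals))]
        a = assess_doe(measured, predicted, small_grid)
        assert a.per_set[0].r == pytest.approx(1.0)
        assert a.per_set[0].lam == 0.0
        assert a.success_rates == {"lenient": 1.0, "stringent": 1.0}

    def test_argmax_one_step_off_passes_stringent_at_lambda_1(self, small_grid):
        base = {c: 0.1 + 0.05 * i for i, c in enumerate(small_grid.conditions)}
        # predicted: same trend but argmax shifted one step (swap top two)
        conds = sorted(base, key=base.get)
        pred = dict(base)
        pred[conds[-1]], pred[conds[-2]] = pred[conds[-2]], pred[conds[-1]]
        lam = float(np.linalg.norm(np.subtract(conds[-1], conds[-2])))
        a = assess_doe(
            [_dtable(small_grid, base)], [_dtable(small_grid, pred)], small_grid
        )
        assert a.per_set[0].lam == pytest.approx(lam)
        if lam <= 1.0 and a.per_set[0].r >= 0.95:
            assert a.per_set[0].passes["stringent"]
        assert a.per_set[0].passes["lenient"]

    def test_anticorrelated_predictions_fail_everything(self, small_grid):
        base = {c: 0.1 + 0.05 * i for i, c in enumerate(small_grid.conditions)}
        pred = {c: 1.0 - v for c, v in base.items()}
        a = assess_doe(
            [_dtable(small_grid, base)], [_dtable(small_grid, pred)], small_grid
        )
        assert a.success_rates == {"lenient": 0.0, "stringent": 0.0}

    def test_stringent_never_exceeds_lenient(self, synthetic_case):
        wgrid = WeightGrid.default(3)
        a, _ = doe_baseline_assessment(
            synthetic_case.grid, synthetic_case.table, synthetic_case.defs, wgrid
        )
        assert a.n_sets == 27
        assert a.success_rates["stringent"] <= a.success_rates["lenient"]


class TestEndToEndRecovery:
    def test_noiseless_quartic_family_data_recovered_perfectly(self, case_grid):
        """Data generated inside the quartic family -> r=1, lambda=0 for all sets."""
        conds = case_grid.conditions
        y1 = {c: 40.0 + 5.0 * c[0] + 3.0 * c[2] + 0.5 * c[0] * c[2] for c in conds}
        y2 = {c: 500.0 + 30.0 * c[2] ** 2 - 15.0 * c[1] for c in conds}
        y3 = {c: 900.0 - 40.0 * c[0] + 25.0 * c[1] * c[2] for c in conds}
        entries = {
            c: ((y1[c], y2[c], y3[c]), (y1[c], y2[c], y3[c])) for c in conds
        }
        table = MeasurementTable(
            grid=case_grid,
            response_names=("Yield", "HCP", "DNA"),
            entries=entries,
        )
        defs = (
            ResponseDef(
                name="Yield", goal="maximize",
                T=max(y1.values()), L=min(y1.values()) - 1.0,
            ),
            ResponseDef(
                name="HCP", goal="minimize",
                T=min(y2.values()), U=max(y2.values()) + 1.0,
            ),
            ResponseDef(
                name="DNA", goal="minimize",
                T=min(y3.values()), U=max(y3.values()) + 1.0,
            ),
        )
        assessment, models = doe_baseline_assessment(
            case_grid, table, defs, WeightGrid.default(3)
        )
        assert assessment.n_sets == 27
        for rec in assessment.per_set:
            assert rec.r == pytest.approx(1.0, abs=1e-9)
            assert rec.lam == 0.0
        assert assessment.success_rates == {"lenient": 1.0, "stringent": 1.0}
        for m in models:
            assert m.rmse == pytest.approx(0.0, abs=1e-7)
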