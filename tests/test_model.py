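import numpy as np
import pytest

from segqc.model import (
    QCModel,
    QualityRegression,
    predict,
    select_lambda,
    selected_features,
    train,
)
from segqc.radiomics import FEATURE_NAMES


def sparse_problem(seed=0, n=200, p=40, idx=(3, 11, 25), coefs=(8.0, -6.0, 4.0), noise=2.0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[list(idx)] = coefs
    y = np.clip(70 + x @ beta + rng.normal(0, noise, n), 0, 100)
    return x, y, beta


class TestTrain:
    def test_huge_lambda_shrinks_everything(self):
        x, y, _ = sparse_problem()
        m = train(x, y, 1e6)
        assert np.count_nonzero(m.coef) == 0
        assert np.allclose(m.predict_array(x), y.mean())

    def test_ols_limit_recovers_noiseless_line(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((60, 1))
        y = np.clip(2.0 * x[:, 0] + 50.0, 0, 100)
        m = train(x, y, 1e-12)
        slope_original_scale = m.coef[0] / m.sds[0]
        intercept = m.intercept - (m.coef * m.means / m.sds).sum()
        assert slope_original_scale == pytest.approx(2.0, abs=1e-6)
        assert intercept == pytest.approx(50.0, abs=1e-6)

    def test_constant_response_gives_intercept_only(self):
        x, _, _ = sparse_problem()
        y = np.full(len(x), 80.0)
        m = train(x, y, 0.5)
        assert np.count_nonzero(m.coef) == 0 and m.intercept == 80.0

    def test_zero_sd_feature_gets_zero_coefficient(self):
        x, y, _ = sparse_problem()
        x[:, 7] = 3.14
        m = train(x, y, 0.1)
        assert m.coef[7] == 0.0

    def test_length_mismatch_rejected(self):
        x, y, _ = sparse_problem()
        with pytest.raises(ValueError, match="rows"):
            train(x, y[:-1], 0.1)

    def test_shrinkage_monotone_along_path(self):
        x, y, _ = sparse_problem()
        grid = np.logspace(1, -3, 20)
        counts = [np.count_nonzero(train(x, y, lam).coef) for lam in grid]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_json_round_trip(self, tmp_path):
        x, y, _ = sparse_problem()
        m = train(x, y, 0.1)
        path = str(tmp_path / "model.json")
        m.to_json(path)
        back = QCModel.from_json(path)
        assert np.allclose(back.coef, m.coef)
        assert np.allclose(back.predict_array(x), m.predict_array(x))


class TestSelectLambda:
    def test_noiseless_data_chooses_small_lambda(self):
        x, y, _ = sparse_problem(noise=1e-6)
        res = select_lambda(x, y, k=5, seed=0)
        assert res.chosen_lambda <= res.grid.max() * 1e-2
        assert res.cv_mse.min() < 0.5

    def test_deterministic_in_seed(self):
        x, y, _ = sparse_problem()
        a = select_lambda(x, y, seed=7)
        b = select_lambda(x, y, seed=7)
        assert a.chosen_lambda == b.chosen_lambda
        assert a.fold_assignment == b.fold_assignment

    def test_patient_grouping_shares_folds(self):
        x, y, _ = sparse_problem(n=200)
        pids = [f"pt{i // 4}" for i in range(200)]  # 4 segmentations/patient
        res = select_lambda(x, y, patient_ids=pids, seed=1)
        folds = res.fold_assignment
        assert set(folds) == set(pids)
        assert max(folds.values()) == 4

    def test_empty_grid_rejected(self):
        x, y, _ = sparse_problem()
        with pytest.raises(ValueError, match="grid"):
            select_lambda(x, y, grid=[])

    def test_bias_diagnostics_reported(self):
        x, y, _ = sparse_problem()
        res = select_lambda(x, y, seed=0)
        assert res.bias.shape == res.grid.shape
        i = np.flatnonzero(res.grid == res.chosen_lambda)[0]
        assert abs(res.bias[i]) <= 1.0 or res.fallback


class TestPredict:
    def _unit_model(self, raw_output):
        names = ("a", "b")
        return QCModel(
            names,
            np.zeros(2),
            np.ones(2),
            np.zeros(2),
            float(raw_output),
            0.1,
        )

    @pytest.mark.parametrize("raw,expected", [(110.0, 100.0), (-3.0, 0.0), (82.5, 82.5)])
    def test_clamping_rule(self, raw, expected):
        m = self._unit_model(raw)
        assert predict(m, np.zeros((1, 2)))[0] == expected

    def test_feature_name_mismatch_lists_names(self):
        import pandas as pd

        m = self._unit_model(50.0)
        df = pd.DataFrame({"a": [1.0], "c": [2.0]})
        with pytest.raises(ValueError, match="missing.*'b'"):
            predict(m, df)

    def test_all_predictions_in_range(self):
        x, y, _ = sparse_problem()
        m = train(x, y, 0.05)
        out = m.predict_array(np.vstack([x * 5, -x * 5]))
        assert np.all((out >= 0) & (out <= 100))


class TestSelectedFeatures:
    def test_all_zero_model_empty_report(self):
        x, y, _ = sparse_problem()
        m = train(x, y, 1e6)
        rep = selected_features(m)
        assert rep["n_selected"].sum() == 0

    def test_totals_match_nonzero_count(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((60, 321))
        beta = np.zeros(321)
        beta[[0, 50, 100, 200, 300]] = [9, 8, -7, 6, 5]
        y = np.clip(60 + x @ beta, 0, 100)
        m = train(x, y, 0.2, feature_names=FEATURE_NAMES)
        rep = selected_features(m)
        by_class = rep.loc["class", "n_selected"].sum()
        by_region = rep.loc["region", "n_selected"].sum()
        assert by_class == by_region == m.n_selected > 0
        assert (
            rep["pct_selected"]
            == 100.0 * rep["n_selected"] / rep["n_total"]
        ).all()


class TestQualityRegressionAPI:
    def test_fit_returns_results_with_summary(self):
        x, y, _ = sparse_problem(n=120)
        res = QualityRegression(x, y).fit(cv=3, seed=0)
        text = res.summary()
        assert "lambda" in text and "selected features" in text
        assert res.lambda_ == res.qc_model.lam
        assert len(res.params) == x.shape[1] + 1

    def test_from_dataframe(self):
        import pandas as pd

        x, y, _ = sparse_problem(n=60, p=5, idx=(0, 2), coefs=(8.0, -6.0))
        df = pd.DataFrame(x, columns=[f"f{i}" for i in range(5)])
        df["rqs"] = y
        df["patient_id"] = [f"p{i//2}" for i in range(60)]
        reg = QualityRegression.from_dataframe(df)
        assert reg.exog.shape == (60, 5)
        res = reg.fit(lam=0.1)
        assert np.all((res.predict() >= 0) & (res.predict() <= 100))
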