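"""Importance analysis: correlation maps against longhand formulas,
Kernel SHAP against closed-form and brute-force Shapley enumeration,
contribution normalisation and the drop-based importance cutoff."""

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression

from spineshape.sensitivity import (
    SensitivityReport,
    ShapConfig,
    analyse,
    contribution_percentages,
    correlation_map,
    importance_cutoff,
    kernel_shap,
)


class TestCorrelationMap:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(30, 3))
        table = correlation_map(W, {"y": 2.0 * W[:, 0]})
        row = table[(table["mode"] == 1)].iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["spearman_rho"] == pytest.approx(1.0)
        assert row["pearson_p"] < 1e-12
        assert row["pearson_significant"]

    def test_monotone_nonlinear_relation(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=40)
        table = correlation_map(w[:, None], {"y": w**3})
        row = table.iloc[0]
        assert row["spearman_rho"] == pytest.approx(1.0)
        assert row["pearson_r"] < 1.0

    def test_matches_longhand_formulas(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = 0.4 * x + rng.normal(size=12)
        table = correlation_map(x[:, None], {"y": y})
        row = table.iloc[0]
        # explicit Pearson formula
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert row["pearson_r"] == pytest.approx(r, abs=1e-12)
        # t-transform two-sided p at n-2 dof
        from scipy import stats

        t = r * np.sqrt(10 / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), 10)
        assert row["pearson_p"] == pytest.approx(p, rel=1e-9)
        # Spearman on average ranks
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rho = np.corrcoef(rx, ry)[0, 1]
        assert row["spearman_rho"] == pytest.approx(rho, abs=1e-12)

    def test_constant_column_reported_undefined(self):
        rng = np.random.default_rng(3)
        W = np.column_stack([np.full(10, 2.0), rng.normal(size=10)])
        table = correlation_map(W, {"y": rng.normal(size=10)})
        row = table[table["mode"] == 1].iloc[0]
        assert row["undefined"]
        assert np.isnan(row["pearson_r"])
        assert not row["pearson_significant"]

    def test_pearson_close_to_spearman_on_linear_response(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(500, 4))
        y = W @ [1.0, -0.5, 0.2, 0.1] + 0.3 * rng.normal(size=500)
        table = correlation_map(W, {"y": y})
        assert np.all(
            np.abs(table["pearson_r"] - table["spearman_rho"]) < 0.05
        )


class TestKernelShap:
    def test_single_mode_equals_delta(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 1))
        y = 3.0 * x[:, 0] + 1.0
        phi = kernel_shap(x, y, ShapConfig(n_coalitions=4))
        f = LinearRegression().fit(x, y)
        delta = f.predict(x) - f.predict(x.mean(0, keepdims=True))
        np.testing.assert_allclose(phi[:, 0], delta, atol=1e-10)

    def test_linear_closed_form(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 6)) @ np.diag([3, 2, 1.5, 1, 0.5, 0.2])
        beta = np.array([1.0, -2.0, 0.5, 0.0, 1.5, -0.3])
        y = 0.7 + X @ beta
        phi = kernel_shap(X, y, ShapConfig(n_coalitions=40, seed=1))
        closed = beta * (X - X.mean(axis=0))
        assert np.abs(phi - closed).max() <= 1e-6

    def test_exhaustive_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(7)
        M = 5
        X = rng.normal(size=(30, M))
        y = X @ rng.normal(size=M) + 0.2 * rng.normal(size=30)
        phi = kernel_shap(X, y, ShapConfig(n_coalitions=2**M))
        f = LinearRegression().fit(X, y)
        b = X.mean(axis=0)
        x = X[4]

        def value(subset):
            z = b.copy()
            z[list(subset)] = x[list(subset)]
            return f.predict(z[None, :])[0]

        brute = np.zeros(M)
        for i in range(M):
            others = [j for j in range(M) if j != i]
            for r in range(M):
                for S in combinations(others, r):
                    w = factorial(len(S)) * factorial(M - len(S) - 1) / factorial(M)
                    brute[i] += w * (value(S + (i,)) - value(S))
        assert np.abs(phi[4] - brute).max() <= 1e-6

    def test_local_accuracy_for_every_subject(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=40)
        config = ShapConfig(n_coalitions=64, seed=2)
        phi = kernel_shap(X, y, config)
        f = LinearRegression().fit(X, y)
        delta = f.predict(X) - f.predict(X.mean(0, keepdims=True))
        assert np.abs(phi.sum(axis=1) - delta).max() <= 1e-6

    def test_underdetermined_budget_rejected(self):
        X = np.random.default_rng(9).normal(size=(30, 6))
        with pytest.raises(ValueError, match="underdetermine"):
            kernel_shap(X, X[:, 0], ShapConfig(n_coalitions=5))

    def test_more_modes_than_subjects_rejected(self):
        X = np.random.default_rng(10).normal(size=(5, 6))
        with pytest.raises(ValueError, match="more subjects"):
            kernel_shap(X, X[:, 0], ShapConfig(n_coalitions=64))


class TestContributions:
    def test_single_active_mode_gets_everything(self):
        phi = np.zeros((10, 4))
        phi[:, 0] = np.random.default_rng(11).normal(size=10)
        pct = contribution_percentages(phi)
        assert pct[0] == pytest.approx(100.0)
        assert np.all(pct[1:] == 0.0)

    def test_sums_to_one_hundred(self):
        phi = np.random.default_rng(12).normal(size=(25, 7))
        assert contribution_percentages(phi).sum() == pytest.approx(100.0, abs=1e-6)

    def test_all_zero_reported_nan(self):
        pct = contribution_percentages(np.zeros((5, 3)))
        assert np.all(np.isnan(pct))


class TestImportanceCutoff:
    def test_unambiguous_gap(self):
        assert importance_cutoff(np.array([40.0, 30.0, 5.0, 5.0, 3.0])) == [0, 1]

    def test_uniform_contributions_empty(self):
        assert importance_cutoff(np.array([12.5] * 8)) == []

    def test_drop_after_rank_four_dominates(self):
        pct = np.array([17.0, 8.0, 6.0, 5.0, 1.5, 1.4, 1.2, 1.0])
        # enumerate consecutive relative drops: the largest is after rank 4
        drops = (pct[:-1] - pct[1:]) / pct[:-1]
        assert np.argmax(drops[:7]) == 3
        assert importance_cutoff(pct) == [0, 1, 2, 3]

    def test_returns_modes_in_contribution_order(self):
        pct = np.array([5.0, 40.0, 30.0, 4.0])
        assert importance_cutoff(pct) == [1, 2]

    def test_too_few_modes_rejected(self):
        with pytest.raises(ValueError):
            importance_cutoff(np.array([100.0]))


class TestAnalyse:
    def test_known_linear_response_ordering(self):
        rng = np.random.default_rng(13)
        sd = np.array([3.0, 2.0, 1.0, 0.5])
        W = rng.normal(size=(200, 4)) * sd
        beta = np.array([2.0, -1.0, 0.5, 0.1])
        outcomes = pd.DataFrame({"y": W @ beta + 0.1 * rng.normal(size=200)})
        report = analyse(W, outcomes, shap_config=ShapConfig(n_coalitions=16))
        expected_order = np.argsort(-np.abs(beta) * sd)
        assert list(report.ranks["y"].to_numpy().argsort()) == list(expected_order)

    def test_listwise_dropping_of_invalid_subjects(self):
        rng = np.random.default_rng(14)
        W = rng.normal(size=(30, 2))
        outcomes = pd.DataFrame({"y": W[:, 0] + rng.normal(size=30)})
        valid = np.ones(30, dtype=bool)
        valid[:5] = False
        report = analyse(W, outcomes, valid=valid,
                         shap_config=ShapConfig(n_coalitions=4))
        assert report.n_subjects == 25
        assert report.shap_values["y"].shape == (25, 2)

    def test_report_serialisation(self, tmp_path):
        rng = np.random.default_rng(15)
        W = rng.normal(size=(40, 3))
        outcomes = pd.DataFrame({"idp": W @ [1, 0.5, 0.2],
                                 "fcp": W @ [0.1, 2.0, 0.2]})
        report = analyse(W, outcomes, shap_config=ShapConfig(n_coalitions=8))
        report.to_json(tmp_path / "report.json")
        report.to_csv(tmp_path / "report.csv")
        import json

        payload = json.loads((tmp_path / "report.json").read_text())
        assert set(payload["contribution_pct"]) == {"idp", "fcp"}
        assert isinstance(report, SensitivityReport)
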