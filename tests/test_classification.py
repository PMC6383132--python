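import numpy as np
import pandas as pd
import pytest
from scipy import stats

from funcdens.classification import (
    MissingParameterError,
    auc,
    auc_bootstrap_ci,
    compare_feature_sets,
    delong_test,
    delong_variance,
    label_variants,
    lof_label,
    logistic_fit,
    roc_points,
)

from conftest import nv


class TestLofLabels:
    @pytest.mark.parametrize(
        "gene,params,expect_lof,expect_basis",
        [
            ("SCN5A", {"peak_current": 36.0}, True, "peak_rule"),
            ("SCN5A", {"peak_current": 82.0}, False, "peak_rule"),
            ("SCN5A", {"peak_current": 50.0}, False, "peak_rule"),       # strict <
            ("KCNQ1", {"peak_current": 80.0, "v_half_act": 23.8}, True, "both"),
            ("KCNQ1", {"peak_current": 59.0, "v_half_act": 0.0}, False, "both"),
            ("KCNQ1", {"peak_current": 17.0}, True, "peak_rule"),
            ("KCNQ1", {"v_half_act": 10.0}, False, "vhalf_rule"),        # strict >
            ("KCNQ1", {"v_half_act": 10.1}, True, "vhalf_rule"),
        ],
    )
    def test_threshold_rules(self, gene, params, expect_lof, expect_basis):
        label = lof_label(gene, 100, "K", params)
        assert label.is_lof is expect_lof
        assert label.basis == expect_basis

    def test_missing_required_parameter_excluded(self):
        with pytest.raises(MissingParameterError):
            lof_label("SCN5A", 100, "K", {"v_half_act": 30.0})
        with pytest.raises(MissingParameterError):
            lof_label("KCNQ1", 100, "K", {"late_current": 300.0})

    def test_unknown_gene_needs_explicit_rules(self):
        with pytest.raises(ValueError):
            lof_label("HERG", 100, "K", {"peak_current": 10.0})
        label = lof_label("HERG", 100, "K", {"peak_current": 10.0}, rules=("peak_current",))
        assert label.is_lof

    def test_monotone_in_peak_current(self):
        # decreasing peak current can never flip LOF back to not-LOF
        labels = [lof_label("SCN5A", 1, "K", {"peak_current": p}).is_lof
                  for p in np.linspace(120, 0, 60)]
        assert sorted(labels) == labels  # False... then True... once crossed

    def test_label_variants_groups_parameters_and_reports_exclusions(self):
        variants = [
            nv(10, alt="K", delta=30.0),                                  # LOF
            nv(11, alt="Q", delta=90.0),                                  # not LOF
            nv(12, alt="E", delta=4.0, parameter="v_half_act"),           # no peak -> excluded
        ]
        labels, excluded = label_variants(variants)
        assert {(l.seq_position, l.is_lof) for l in labels} == {(10, True), (11, False)}
        assert len(excluded) == 1 and excluded[0][0][1] == 12


class TestAuc:
    def test_perfect_and_reversed_ranking(self):
        y = np.array([0, 0, 1, 1], dtype=bool)
        assert auc([0.1, 0.2, 0.8, 0.9], y) == 1.0
        assert auc([0.9, 0.8, 0.2, 0.1], y) == 0.0

    def test_equals_pairwise_probability_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 60))
            scores = np.round(rng.normal(size=n), 1)
            y = rng.random(n) < 0.5
            if y.sum() in (0, n):
                continue
            pos, neg = scores[y], scores[~y]
            brute = (
                np.sum(pos[:, None] > neg[None, :]) + 0.5 * np.sum(pos[:, None] == neg[None, :])
            ) / (len(pos) * len(neg))
            assert auc(scores, y) == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestLogisticFit:
    def test_separable_feature_reaches_auc_one(self):
        y = np.array([0] * 15 + [1] * 15, dtype=bool)
        X = pd.DataFrame({"f": np.concatenate([np.zeros(15), np.ones(15)])})
        scorer = logistic_fit(X, y)
        assert auc(scorer.predict_proba(X), y) == 1.0

    def test_uninformative_feature_scores_near_chance(self):
        rng = np.random.default_rng(0)
        y = rng.random(500) < 0.5
        X = pd.DataFrame({"f": rng.normal(size=500)})
        scorer = logistic_fit(X, y)
        assert auc(scorer.predict_proba(X), y) == pytest.approx(0.5, abs=0.05)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(1)
        y = rng.random(100) < 0.5
        X = pd.DataFrame({"f": rng.normal(size=100), "g": rng.normal(size=100)})
        s1 = logistic_fit(X, y).predict_proba(X)
        s2 = logistic_fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(s1, s2)

    def test_guards(self):
        X = pd.DataFrame({"f": np.arange(30.0)})
        with pytest.raises(ValueError):
            logistic_fit(X, np.ones(30, dtype=bool))
        with pytest.raises(ValueError):
            logistic_fit(X.iloc[:10], np.array([0, 1] * 5, dtype=bool))


class TestBootstrapCI:
    def test_perfect_ranking_gives_degenerate_interval(self):
        y = np.array([0] * 20 + [1] * 20, dtype=bool)
        s = np.concatenate([np.zeros(20), np.ones(20)])
        assert auc_bootstrap_ci(s, y, B=200, seed=0) == (1.0, 1.0)

    def test_same_seed_same_interval(self, rng):
        y = rng.random(80) < 0.5
        s = rng.normal(size=80)
        assert auc_bootstrap_ci(s, y, B=300, seed=7) == auc_bootstrap_ci(s, y, B=300, seed=7)


class TestDeLong:
    def test_identical_scores_give_null_result(self, rng):
        y = rng.random(100) < 0.5
        s = rng.normal(size=100)
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            delong_test(np.zeros(10), np.zeros(12), np.zeros(10, dtype=bool))

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(4)
        y = np.zeros(300, dtype=bool)
        y[:150] = True
        ps = []
        for _ in range(2000):
            ps.append(delong_test(rng.normal(size=300), rng.normal(size=300), y)[1])
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.05

    def test_variance_component_matches_bootstrap_variance(self):
        rng = np.random.default_rng(17)
        y = np.zeros(500, dtype=bool)
        y[:250] = True
        s = rng.normal(size=500)
        dv = delong_variance(s, y)
        boots = []
        for _ in range(800):
            ip = rng.integers(0, 250, 250)
            iq = 250 + rng.integers(0, 250, 250)
            idx = np.concatenate([ip, iq])
            boots.append(auc(s[idx], y[idx]))
        bv = np.var(boots, ddof=1)
        assert dv == pytest.approx(bv, rel=0.2)

    def test_detects_a_genuinely_better_classifier(self):
        # power: adding the generative feature should win the DeLong contrast
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 200
            latent = rng.normal(size=n)
            y = latent + rng.normal(0, 0.6, size=n) > 0
            noise = rng.normal(size=(n, 2))
            weak = logistic_fit(pd.DataFrame(noise, columns=["a", "b"]), y)
            strong = logistic_fit(
                pd.DataFrame(np.column_stack([noise, latent]), columns=["a", "b", "t"]), y
            )
            sa = weak.predict_proba(pd.DataFrame(noise, columns=["a", "b"]))
            sb = strong.predict_proba(
                pd.DataFrame(np.column_stack([noise, latent]), columns=["a", "b", "t"])
            )
            wins += delong_test(sa, sb, y)[1] < 0.05
        assert wins >= 80


class TestCompareFeatureSets:
    def _table(self, rng, n=200):
        latent = rng.normal(size=n)
        y = pd.Series(latent + rng.normal(0, 0.7, size=n) > 0)
        table = pd.DataFrame(
            {
                "s1": 0.5 * latent + rng.normal(size=n),
                "s2": 0.4 * latent + rng.normal(size=n),
                "noise": rng.normal(size=n),
                "latent": latent,
            }
        )
        return table, y

    def test_duplicated_spec_produces_identical_aucs(self, rng):
        table, y = self._table(rng)
        cmp_ = compare_feature_sets(
            table, y, {"a": ["s1", "s2"], "b": ["s1", "s2"]}, B=100, seed=0
        )
        assert cmp_.aucs["a"] == cmp_.aucs["b"]
        assert cmp_.contrasts[0][3] == 1.0  # identical models, p = 1

    def test_pure_noise_column_changes_nothing_meaningful(self, rng):
        table, y = self._table(rng)
        cmp_ = compare_feature_sets(
            table, y, {"base": ["s1", "s2"], "plus_noise": ["s1", "s2", "noise"]},
            B=100, seed=0,
        )
        assert abs(cmp_.aucs["base"] - cmp_.aucs["plus_noise"]) < 0.05
        assert cmp_.contrasts[0][3] > 0.05

    def test_models_share_the_same_complete_case_rows(self, rng):
        table, y = self._table(rng)
        table.loc[table.index[:20], "s2"] = np.nan
        cmp_ = compare_feature_sets(
            table, y, {"a": ["s1"], "b": ["s1", "s2"]}, B=100, seed=0
        )
        assert cmp_.n_variants == len(table) - 20

    def test_empty_feature_set_rejected(self, rng):
        table, y = self._table(rng)
        with pytest.raises(ValueError):
            compare_feature_sets(table, y, {"a": []}, B=100)
        with pytest.raises(ValueError):
            compare_feature_sets(table, y, {"a": ["absent_column"]}, B=100)


class TestRocExport:
    def test_curve_spans_unit_square(self, rng):
        y = rng.random(60) < 0.5
        s = rng.normal(size=60)
        roc = roc_points(s, y)
        assert roc["fpr"].iloc[0] == 0.0 and roc["fpr"].iloc[-1] == 1.0
        assert roc["tpr"].iloc[0] == 0.0 and roc["tpr"].iloc[-1] == 1.0
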