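"""Clinical dichotomization, normalization, group tests, attribution."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flimhet.cohort import (
    AttributionConfig,
    ClinicalRecord,
    association_report,
    build_cohort_table,
    dichotomize,
    feature_attribution,
    mann_whitney,
    normality_report,
    point_biserial,
    znormalize,
)
from flimhet.heterogeneity import cells_to_metrics
from flimhet.synthetic import CohortSpec, cohort_truth_table, generate_cohort


def _rec(T=2, N=0, M=0, G=2, stage=""):
    return ClinicalRecord(sample_id="p1", T=T, N=N, M=M, G=G, stage_label=stage)


class TestDichotomize:
    @pytest.mark.parametrize(
        "tnmg, expected",
        [
            ((2, 0, 0, 2), (0, 0, 0)),
            ((3, 1, 0, 3), (1, 1, 1)),
            ((4, 0, 1, 1), (1, 1, 0)),  # M alone triggers the metastasis group
            ((1, 0, 0, 3), (0, 0, 1)),
        ],
    )
    def test_group_coding(self, tnmg, expected):
        assert dichotomize(_rec(*tnmg)) == expected

    def test_out_of_range_codes_rejected(self):
        with pytest.raises(ValueError, match="T"):
            _rec(T=5)
        with pytest.raises(ValueError, match="G"):
            _rec(G=0)

    def test_stage_label_consistency(self):
        _rec(T=2, stage="I")  # valid
        _rec(T=3, N=1, stage="IIIB")  # valid
        with pytest.raises(ValueError, match="inconsistent"):
            _rec(T=2, stage="IV")

    def test_pure_function_of_codes(self):
        recs = [_rec(T=t, N=n, M=m, G=g)
                for t in (1, 4) for n in (0, 1) for m in (0, 1) for g in (1, 3)]
        assert [dichotomize(r) for r in recs] == [dichotomize(r) for r in recs]


class TestZnormalize:
    def test_two_point_closed_form(self):
        df = pd.DataFrame({"d": [2.19, 11.99]})
        out = znormalize(df, ["d"])
        np.testing.assert_allclose(out["d"], [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(0, 1, 40)})
        once = znormalize(df, ["x"])
        twice = znormalize(once, ["x"])
        np.testing.assert_allclose(once["x"], twice["x"], atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(5, 2, 30)})
        shifted = df + 17.0
        np.testing.assert_allclose(
            znormalize(df, ["x"])["x"], znormalize(shifted, ["x"])["x"], atol=1e-9
        )

    def test_zero_variance_names_column(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            znormalize(df, ["flat"])


def _mw_enumeration_p(x0, x1):
    """Brute-force two-sided p: U over every possible group-0 assignment."""
    pooled = np.concatenate([x0, x1])
    n0 = len(x0)

    def u_stat(idx0):
        a = pooled[list(idx0)]
        b = np.delete(pooled, list(idx0))
        return sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)

    u_obs = u_stat(range(n0))
    mid = n0 * (len(x1)) / 2.0
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n0)]
    extreme = sum(abs(u - mid) >= abs(u_obs - mid) - 1e-12 for u in us)
    return extreme / len(us)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 assignments as extreme

    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_path_matches_enumeration(self):
        """The exact small-sample path agrees with full enumeration over all
        group assignments (combined n <= 10, no ties)."""
        rng = np.random.default_rng(7)
        for _ in range(12):
            n0 = rng.integers(2, 5)
            n1 = rng.integers(2, 6)
            vals = rng.permutation(np.arange(1.0, n0 + n1 + 1))
            groups = np.array([0] * n0 + [1] * n1)
            _, p = mann_whitney(vals, groups)
            p_enum = _mw_enumeration_p(vals[groups == 0], vals[groups == 1])
            assert p == pytest.approx(p_enum, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([1.0, 2.0], [0, 0])


class TestPointBiserial:
    def test_equals_scipy_definitional_identity(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 15)
        x = rng.normal(0, 1, 30) + y
        r = point_biserial(y, x)
        assert r == pytest.approx(stats.pointbiserialr(y, x).statistic, abs=1e-12)

    def test_perfect_separation_approaches_one(self):
        y = np.array([0] * 5 + [1] * 5)
        x = np.array([1.0] * 5 + [2.0] * 5) + np.linspace(0, 1e-9, 10)
        assert point_biserial(y, x) > 0.999

    def test_permutation_null_centers_on_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        y = np.array([0] * 20 + [1] * 20)
        rs = []
        for _ in range(500):
            rs.append(point_biserial(rng.permutation(y), x))
        assert abs(np.mean(rs)) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both label classes"):
            point_biserial([1, 1, 1], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def planted_table():
    """Cohort whose groups differ only in the spread of a1."""
    samples = generate_cohort(CohortSpec(seed=1))
    metrics = cells_to_metrics(cohort_truth_table(samples), seed=1)
    return build_cohort_table(metrics, [s.clinical for s in samples])


class TestCohortTable:
    def test_z_columns_standardized(self, planted_table):
        for f in ("z_D_a1", "z_BI_tau2"):
            col = planted_table[f]
            assert abs(col.mean()) < 1e-9
            assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_groups_binary(self, planted_table):
        for g in ("T_group", "NM_group", "G_group"):
            assert set(planted_table[g].unique()) <= {0, 1}


class TestFeatureAttribution:
    def test_planted_signal_ranked_first(self, planted_table):
        attr = feature_attribution(planted_table, "G_group", AttributionConfig(seed=1))
        assert attr.ranking[0] == "z_D_a1"

    def test_additivity(self, planted_table):
        attr = feature_attribution(planted_table, "G_group", AttributionConfig(seed=0))
        pred = attr.model.predict_proba(
            planted_table[attr.features].to_numpy()
        )[:, 1]
        total = attr.shap_values.sum(axis=1).to_numpy() + attr.base_value
        np.testing.assert_allclose(total, pred, atol=1e-10)

    def test_shuffled_labels_spread_attribution_evenly(self, planted_table):
        rng = np.random.default_rng(0)
        table = planted_table.copy()
        means = []
        for rep in range(20):
            table["y"] = rng.permutation(table["G_group"].to_numpy())
            if table["y"].nunique() < 2:
                continue
            attr = feature_attribution(
                table, "y", AttributionConfig(seed=rep, n_trees=200)
            )
            means.append(attr.importances.reindex(attr.features).to_numpy())
        agg = np.mean(means, axis=0)
        assert agg.max() <= 3.0 * np.median(agg)

    def test_duplicated_feature_splits_attribution(self, planted_table):
        table = planted_table.copy()
        table["z_D_a1_copy"] = table["z_D_a1"]
        feats = ["z_D_a1", "z_D_a1_copy", "z_D_tau_m", "z_D_tau2",
                 "z_BI_a1", "z_BI_tau_m", "z_BI_tau2"]
        # all-features splitting keeps the forest structure comparable, so the
        # comparison isolates Shapley credit-sharing from feature-subsampling
        cfg = AttributionConfig(seed=3, max_features=None)
        base = feature_attribution(planted_table, "G_group", cfg)
        dup = feature_attribution(table, "G_group", cfg, features=feats)
        orig = base.shap_values["z_D_a1"].abs().mean()
        combined = (
            (dup.shap_values["z_D_a1"] + dup.shap_values["z_D_a1_copy"]).abs().mean()
        )
        assert combined == pytest.approx(orig, rel=0.25)
        # and each duplicate individually carries less than the original
        assert dup.shap_values["z_D_a1"].abs().mean() < orig

    def test_target_cannot_be_a_feature(self, planted_table):
        with pytest.raises(ValueError, match="target column"):
            feature_attribution(
                planted_table,
                "G_group",
                features=["G_group", "z_D_a1", "z_D_tau_m", "z_D_tau2",
                          "z_BI_a1", "z_BI_tau_m"],
            )

    def test_single_class_target_rejected(self, planted_table):
        table = planted_table.copy()
        table["const"] = 1
        with pytest.raises(ValueError, match="single class"):
            feature_attribution(table, "const")

    def test_interventional_mode_also_additive(self, planted_table):
        attr = feature_attribution(
            planted_table, "G_group",
            AttributionConfig(seed=0, n_trees=100, shap_mode="interventional"),
        )
        pred = attr.model.predict_proba(planted_table[attr.features].to_numpy())[:, 1]
        total = attr.shap_values.sum(axis=1).to_numpy() + attr.base_value
        np.testing.assert_allclose(total, pred, atol=1e-10)


class TestAssociationReport:
    def test_planted_effect_detected(self, planted_table):
        report = association_report(planted_table, "G_group")
        row = report[report["feature"] == "D_a1"].iloc[0]
        assert row["p_value"] < 0.05
        assert row["shap_rank"] == 1
        assert row["point_biserial_r"] > 0.5
        assert set(report["feature"]) == {
            "D_a1", "D_tau_m", "D_tau2", "BI_a1", "BI_tau_m", "BI_tau2"
        }

    def test_holm_adjustment_monotone(self, planted_table):
        report = association_report(planted_table, "G_group", holm=True)
        assert (report["p_holm"] >= report["p_value"] - 1e-12).all()


def test_normality_report_screens_only():
    rng = np.random.default_rng(0)
    stat, p = normality_report(rng.normal(0, 1, 200))
    assert 0 <= stat <= 1 and p > 0.01
    stat2, p2 = normality_report(rng.exponential(1, 200))
    assert p2 < 0.01
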