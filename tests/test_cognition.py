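import numpy as np
import pandas as pd
import pytest

from netcog import cognition, synth
from .conftest import exact_correlation_data


def make_subject_table(n=60, missing=None, seed=0):
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "age": rng.uniform(55, 85, n),
            "sex": rng.integers(0, 2, n),
            "education": rng.integers(1, 11, n),
            "screening": rng.integers(9, 19, n),
        }
    )
    for i in range(1, 15):
        table[f"test_{i:02d}"] = rng.standard_normal(n)
    if missing:
        for (row, col) in missing:
            table.iloc[row, table.columns.get_loc(col)] = np.nan
    return table


class TestScreening:
    def test_low_screening_excluded(self):
        table = make_subject_table(10)
        table.loc[0, "screening"] = 8
        table.loc[1, "screening"] = 9
        kept, log = cognition.screen_subjects(table)
        assert 0 not in kept.index and 1 in kept.index
        assert "below cutoff" in log.iloc[0]["reason"]

    def test_missing_test_threshold(self):
        table = make_subject_table(10)
        for c in ["test_01", "test_02", "test_03", "test_04"]:
            table.loc[2, c] = np.nan
        for c in ["test_01", "test_02", "test_03"]:
            table.loc[3, c] = np.nan
        kept, log = cognition.screen_subjects(table)
        assert 2 not in kept.index  # 4 missing -> excluded
        assert 3 in kept.index  # 3 missing -> retained

    def test_complete_cohort_untouched(self):
        table = make_subject_table(20)
        kept, log = cognition.screen_subjects(table)
        assert len(kept) == 20 and log.empty


class TestImputation:
    def test_cell_median_value(self):
        table = make_subject_table(8, seed=1)
        table["sex"] = 0
        table["age"] = 60.0
        table.loc[:, "test_01"] = [10, 12, 14, np.nan, 10, 12, 14, 12]
        out = cognition.impute_by_cell(table)
        assert out.loc[3, "test_01"] == 12

    def test_nonmissing_cells_never_altered(self):
        table = make_subject_table(40, seed=2)
        table.loc[5, "test_03"] = np.nan
        out = cognition.impute_by_cell(table)
        mask = ~table["test_03"].isna()
        pd.testing.assert_series_equal(out.loc[mask, "test_03"], table.loc[mask, "test_03"])
        assert not out["test_03"].isna().any()

    def test_mcar_missing_preserves_column_means(self):
        parc = synth.make_parcellation(4, 2)
        spec = synth.CohortSpec(n_subjects=400, timepoints=16, seed=5)
        battery = synth.BatterySpec(missing_rate=0.05)
        cohort = synth.generate_cohort(parc, spec, battery=battery)
        table = cohort.battery_raw.copy()
        table["age"] = cohort.confounds["age"].to_numpy()
        table["sex"] = cohort.confounds["sex"].to_numpy()
        out = cognition.impute_by_cell(table)
        for col in [c for c in table.columns if c.startswith("test_")]:
            sd = table[col].std()
            assert abs(out[col].mean() - table[col].mean()) < 0.1 * sd


class TestZScore:
    def test_population_z(self):
        table = pd.DataFrame({"test_01": [1.0, 2.0, 3.0], "age": [60, 61, 62],
                              "sex": [0, 1, 0]})
        z = cognition.invert_zscore(table)
        np.testing.assert_allclose(z["test_01"], [-1.2247, 0, 1.2247], atol=1e-4)

    def test_invert_flag_reverses_order(self):
        table = pd.DataFrame({"test_01": [1.0, 2.0, 3.0]})
        z = cognition.invert_zscore(table, invert_flags=[True])
        assert z["test_01"].iloc[0] > z["test_01"].iloc[2]

    def test_zero_variance_rejected(self):
        table = pd.DataFrame({"test_01": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero variance"):
            cognition.invert_zscore(table)

    def test_moments_property(self):
        table = make_subject_table(50, seed=3)
        z = cognition.invert_zscore(table)
        assert np.allclose(z.mean(), 0, atol=1e-10)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-10)


class TestKMO:
    def test_equicorrelated_closed_form(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        X = exact_correlation_data(R, n=200, seed=4)
        # partial correlation r/(1+r) = 1/3; KMO = 6*0.25/(6*0.25+6/9)
        assert cognition.kmo_index(X) == pytest.approx(0.25 / (0.25 + 1 / 9), abs=1e-6)

    def test_uncorrelated_battery_low_kmo(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((2000, 6))
        assert cognition.kmo_index(X) < 0.6

    def test_strong_common_factor_high_kmo(self):
        parc = synth.make_parcellation(4, 2)
        spec = synth.CohortSpec(n_subjects=600, timepoints=16, seed=7)
        cohort = synth.generate_cohort(parc, spec)
        z = cognition.invert_zscore(cohort.battery_raw)
        assert cognition.kmo_index(z) >= 0.85


class TestPCA:
    def test_forced_one_component_tracks_general_factor(self):
        parc = synth.make_parcellation(4, 2)
        spec = synth.CohortSpec(n_subjects=500, timepoints=16, seed=8)
        cohort = synth.generate_cohort(parc, spec)
        z = cognition.invert_zscore(cohort.battery_raw)
        sol = cognition.pca_components(z, rule="forced_k", forced_k=1, rotate="none")
        r = np.corrcoef(sol.scores["PC1"], cohort.truth["latent_cognition"])[0, 1]
        assert abs(r) >= 0.8
        # sign convention: largest loading positive implies positive link
        assert r > 0

    def test_scores_uncorrelated_before_rotation(self):
        table = make_subject_table(100, seed=9)
        z = cognition.invert_zscore(table)
        sol = cognition.pca_components(z, rule="forced_k", forced_k=3, rotate="none")
        gram = sol.scores.T @ sol.scores / len(sol.scores)
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_identity_correlation_battery_errors(self):
        R = np.eye(5)
        X = exact_correlation_data(R, n=100, seed=10)
        z = pd.DataFrame(X, columns=[f"test_{i:02d}" for i in range(1, 6)])
        with pytest.raises(ValueError, match="retains no components"):
            cognition.pca_components(z, rule="eigenvalue_gt_1")


class TestStability:
    def test_identical_subsets_perfect_correlation(self):
        table = make_subject_table(60, seed=11)
        z = cognition.invert_zscore(table)
        out = cognition.component_stability(
            z, mode="drop_imputed", complete_mask=np.ones(60, dtype=bool),
            rule="forced_k",
        )
        np.testing.assert_allclose(out["loading_r"], 1.0, atol=1e-10)

    def test_structured_battery_split_half_stable(self):
        parc = synth.make_parcellation(4, 2)
        spec = synth.CohortSpec(n_subjects=300, timepoints=16, seed=19)
        cohort = synth.generate_cohort(parc, spec)
        z = cognition.invert_zscore(cohort.battery_raw)
        out = cognition.component_stability(z, mode="split_half", rng=3)
        assert (out["loading_r"] > 0.86).all()
        assert not out["count_mismatch"].any()

    def test_noise_battery_unstable(self):
        rng = np.random.default_rng(12)
        z = pd.DataFrame(
            rng.standard_normal((120, 8)),
            columns=[f"test_{i:02d}" for i in range(1, 9)],
        )
        z = (z - z.mean()) / z.std(ddof=0)
        out = cognition.component_stability(z, rng=13, rule="forced_k")
        assert out["loading_r"].min() < 0.9


class TestGroups:
    def test_median_split(self):
        g = cognition.make_groups(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(g.labels) == ["low", "low", "high", "high"]

    def test_extreme_quartiles(self):
        g = cognition.make_groups(
            pd.Series(np.arange(1, 101, dtype=float)), scheme="extreme_quartiles"
        )
        assert (g.labels == "low").sum() == 25
        assert (g.labels == "high").sum() == 25
        assert (g.labels == "excluded").sum() == 50

    def test_all_ties_low(self):
        with pytest.warns(UserWarning, match="all scores equal"):
            g = cognition.make_groups(pd.Series([2.0] * 10))
        assert (g.labels == "low").all()

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            cognition.make_groups(pd.Series([1.0, 2.0]))


class TestMatching:
    def _confounded_groups(self, n=400, seed=14):
        rng = np.random.default_rng(seed)
        conf = pd.DataFrame(
            {
                "age": rng.uniform(55, 85, n),
                "sex": rng.integers(0, 2, n),
                "education": np.clip(np.rint(rng.normal(6.5, 1.9, n)), 1, 10),
            }
        )
        z_age = (conf["age"] - conf["age"].mean()) / conf["age"].std()
        score = -0.5 * z_age + rng.standard_normal(n)
        groups = cognition.make_groups(pd.Series(score))
        return groups, conf

    def test_balance_restored(self):
        groups, conf = self._confounded_groups()
        matched = cognition.propensity_match(groups, conf)
        post = matched.balance.query("phase == 'post'")
        pre = matched.balance.query("phase == 'pre'")
        assert pre.loc[pre.covariate == "age", "smd"].abs().iloc[0] > 0.3
        assert post["smd"].abs().max() < 0.15
        assert len(matched.retained) % 2 == 0

    def test_identical_distributions_retain_nearly_all(self):
        rng = np.random.default_rng(15)
        n = 200
        conf = pd.DataFrame(
            {
                "age": rng.uniform(55, 85, n),
                "sex": rng.integers(0, 2, n),
                "education": rng.integers(1, 11, n),
            }
        )
        score = pd.Series(rng.standard_normal(n))
        groups = cognition.make_groups(score)
        matched = cognition.propensity_match(groups, conf)
        # greedy 1:1 matching without replacement loses a little of the
        # distribution tails even under identical group distributions
        assert len(matched.retained) >= 0.75 * n
        post = matched.balance.query("phase == 'post'")
        assert post["smd"].abs().max() < 0.15

    def test_small_groups_rejected(self):
        groups = cognition.make_groups(pd.Series(np.arange(8, dtype=float)))
        conf = pd.DataFrame(
            {"age": np.arange(8) + 60.0, "sex": [0, 1] * 4, "education": [5] * 8}
        )
        with pytest.raises(ValueError, match="at least 10"):
            cognition.propensity_match(groups, conf)


class TestCognitivePCAEstimator:
    def test_fit_transform_roundtrip(self):
        table = make_subject_table(80, seed=16)
        est = cognition.CognitivePCA(rule="forced_k", forced_k=2, rotate="none")
        scores = est.fit(table).transform(table)
        assert scores.shape == (80, 2)
        np.testing.assert_allclose(
            scores.to_numpy(), est.solution_.scores.to_numpy(), atol=1e-8
        )

    def test_sklearn_params_api(self):
        est = cognition.CognitivePCA()
        assert est.get_params()["rule"] == "eigenvalue_gt_1"
        est.set_params(forced_k=3)
        assert est.forced_k == 3


class TestMatchingSymmetry:
    def test_relabelled_groups_give_identical_matched_sample(self):
        rng = np.random.default_rng(20)
        n = 120
        conf = pd.DataFrame(
            {
                "age": rng.uniform(55, 85, n),
                "sex": rng.integers(0, 2, n),
                "education": rng.integers(1, 11, n),
            }
        )
        z_age = (conf["age"] - conf["age"].mean()) / conf["age"].std()
        score = pd.Series(-0.4 * z_age.to_numpy() + rng.standard_normal(n))
        groups = cognition.make_groups(score)
        flipped = cognition.GroupAssignment(
            labels=groups.labels.map({"high": "low", "low": "high"}),
            scheme=groups.scheme,
        )
        a = cognition.propensity_match(groups, conf)
        b = cognition.propensity_match(flipped, conf)
        assert set(a.retained) == set(b.retained)

    def test_matching_deterministic(self):
        rng = np.random.default_rng(21)
        n = 80
        conf = pd.DataFrame(
            {
                "age": rng.uniform(55, 85, n),
                "sex": rng.integers(0, 2, n),
                "education": rng.integers(1, 11, n),
            }
        )
        groups = cognition.make_groups(pd.Series(rng.standard_normal(n)))
        a = cognition.propensity_match(groups, conf)
        b = cognition.propensity_match(groups, conf)
        assert list(a.retained) == list(b.retained)
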