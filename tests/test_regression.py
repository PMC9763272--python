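"""Regression pipeline: standardization, splitting, OLS, selection, validation."""

import numpy as np
import pandas as pd
import pytest

from rmkpredict import (
    PUBLISHED_LOOCV_MODELS,
    GeneratorConfig,
    Standardizer,
    balance_tests,
    design_matrix,
    fit_ols,
    generate_cohort,
    predict_published,
    run_loocv,
    run_ssv,
    select_significant,
    split_sample,
    zscore,
)
from conftest import make_linear_table


class TestStandardize:
    def test_two_point_sample(self):
        z, mean, sd = zscore([0.0, 2.0])
        np.testing.assert_allclose(z, [-0.70710678, 0.70710678])
        assert mean == 1.0
        assert sd == pytest.approx(np.sqrt(2))

    def test_value_at_mean_maps_to_zero(self):
        z, _, _ = zscore([1.0, 2.0, 3.0])
        assert z[1] == 0.0

    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z, _, _ = zscore(rng.normal(10, 3, 50))
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_variable_named_in_error(self, cohort_table):
        df = cohort_table.copy()
        df["age"] = 65.0
        with pytest.raises(ValueError, match="age"):
            Standardizer().fit(df)

    def test_transform_projects_new_cases(self, cohort_table):
        std = Standardizer().fit(cohort_table)
        out = std.transform(cohort_table.iloc[:5])
        expected = (cohort_table["mpe_c"].iloc[:5] - std.means["mpe_c"]) / std.sds["mpe_c"]
        np.testing.assert_allclose(out["mpe_c"], expected)


class TestSplitSample:
    def test_study_size_partition(self, cohort_table):
        split = split_sample(cohort_table, train_frac=0.75, seed=0)
        assert split.n_train == 50
        assert split.n_valid == 16

    def test_exact_quarter(self):
        df = pd.DataFrame({"id": list("abcd")})
        split = split_sample(df, train_frac=0.75, seed=1)
        assert (split.n_train, split.n_valid) == (3, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_is_disjoint_and_exhaustive(self, cohort_table, seed):
        split = split_sample(cohort_table, seed=seed)
        train, valid = set(split.train_ids), set(split.valid_ids)
        assert train.isdisjoint(valid)
        assert train | valid == set(cohort_table["id"])

    def test_invalid_fraction_rejected(self, cohort_table):
        for frac in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                split_sample(cohort_table, train_frac=frac)


class TestBalanceTests:
    def test_identical_sets_show_no_imbalance(self, cohort_table):
        """Training and validation copies of the same records: every test
        statistic is at its null value, p maximal."""
        doubled = pd.concat(
            [
                cohort_table.assign(id=cohort_table["id"] + "_t"),
                cohort_table.assign(id=cohort_table["id"] + "_v"),
            ],
            ignore_index=True,
        )
        split = split_sample(doubled, seed=0)  # only sizes matter below
        split.train_ids = [i for i in doubled["id"] if i.endswith("_t")]
        split.valid_ids = [i for i in doubled["id"] if i.endswith("_v")]
        balance, _ = balance_tests(doubled, split)
        assert (balance["p_value"] > 0.95).all()
        assert not balance["significant"].any()

    def test_study_sex_composition_is_balanced(self):
        """32/18 vs 12/4 male/female counts: chi-square finds no difference."""
        sexes = ["male"] * 32 + ["female"] * 18 + ["male"] * 12 + ["female"] * 4
        ids = [f"P{i:03d}" for i in range(66)]
        df = pd.DataFrame({"id": ids, "sex": sexes})
        split = split_sample(df, seed=0)
        split.train_ids, split.valid_ids = ids[:50], ids[50:]
        balance, _ = balance_tests(df, split)
        row = balance.set_index("variable").loc["sex"]
        assert row["test"] == "chi-square"
        assert row["p_value"] > 0.05

    def test_bonferroni_correction_capped_at_one(self, cohort_table):
        split = split_sample(cohort_table, seed=0)
        _, subgroup = balance_tests(cohort_table, split, seed=0)
        assert (subgroup["p_bonferroni"] <= 1.0).all()
        expected = np.minimum(1.0, subgroup["p_raw"] * 6)
        np.testing.assert_allclose(subgroup["p_bonferroni"], expected)
        # 4 groups -> 6 pairwise comparisons per variable
        assert (subgroup.groupby("variable").size() == 6).all()


class TestFitOls:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 10, 20)
        model = fit_ols(3 + 2 * x, pd.DataFrame({"x": x}))
        assert model.intercept == pytest.approx(3.0)
        assert model.coefficients["x"] == pytest.approx(2.0)
        assert model.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        rng = np.random.default_rng(1)
        model = fit_ols(np.full(15, 7.0), pd.DataFrame({"x": rng.normal(size=15)}))
        assert model.intercept == pytest.approx(7.0)
        assert model.coefficients["x"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Independent oracle: solve (X'X) b = X'y directly."""
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = rng.normal(size=20)
        model = fit_ols(y, X)
        Xc = np.column_stack([np.ones(20), X.to_numpy()])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        np.testing.assert_allclose(
            [model.intercept, *model.coefficients], beta, atol=1e-8
        )

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=12)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="collinear.*'a'.*'b'"):
            fit_ols(rng.normal(size=12), X)

    def test_requires_more_rows_than_parameters(self):
        X = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError, match="more observations"):
            fit_ols([1.0, 2.0, 3.0], X)


class TestSelectSignificant:
    def _signal_design(self, n=200, seed=3):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, 3)), columns=["mpe_c", "mpe_d", "ms_b"]
        )
        y = 10 - 5 * X["mpe_c"] + 3 * X["mpe_d"] + rng.normal(0, 1, n)
        return y, X

    def test_all_significant_model_unchanged(self):
        y, X = self._signal_design()
        X = X[["mpe_c", "mpe_d"]]
        model = select_significant(y, X)
        assert model.predictors == ["mpe_c", "mpe_d"]

    def test_pure_noise_predictor_eliminated(self):
        y, X = self._signal_design()
        model = select_significant(y, X)
        assert "ms_b" not in model.predictors
        assert {"mpe_c", "mpe_d"} <= set(model.predictors)

    def test_alpha_one_keeps_everything(self):
        y, X = self._signal_design()
        model = select_significant(y, X, alpha=1.0)
        assert model.predictors == list(X.columns)

    def test_retained_signs_match_full_model(self):
        y, X = self._signal_design()
        full = fit_ols(y, X)
        reduced = select_significant(y, X)
        for name in reduced.predictors:
            assert np.sign(reduced.coefficients[name]) == np.sign(full.coefficients[name])


class TestRunSSV:
    def test_noiseless_cohort_validates_perfectly(self, linear_table):
        results = run_ssv(linear_table, seed=2, select=False, do_balance=False)
        for res in results.values():
            assert res.valid_report.rmse == pytest.approx(0.0, abs=1e-8)
            assert res.valid_report.r2 == pytest.approx(1.0)
            assert res.train_report.r2 == pytest.approx(1.0)

    def test_no_leakage_between_sets(self, linear_table):
        """Corrupting validation outcomes must not move training metrics."""
        clean = run_ssv(linear_table, outcomes=["ELBOW"], seed=4, do_balance=False)
        corrupted = linear_table.copy()
        valid_ids = clean["ELBOW"].split.valid_ids
        mask = corrupted["id"].isin(valid_ids)
        corrupted.loc[mask, "mi_elbow_t2"] += 7.0
        dirty = run_ssv(corrupted, outcomes=["ELBOW"], seed=4, do_balance=False)
        assert dirty["ELBOW"].train_report.rmse == pytest.approx(
            clean["ELBOW"].train_report.rmse
        )
        assert dirty["ELBOW"].valid_report.rmse > clean["ELBOW"].valid_report.rmse

    def test_seed_determines_partition_deterministically(self, cohort_table):
        a = run_ssv(cohort_table, outcomes=["UL"], seed=9, do_balance=False)
        b = run_ssv(cohort_table, outcomes=["UL"], seed=9, do_balance=False)
        c = run_ssv(cohort_table, outcomes=["UL"], seed=10, do_balance=False)
        assert a["UL"].split.train_ids == b["UL"].split.train_ids
        assert a["UL"].split.train_ids != c["UL"].split.train_ids
        assert a["UL"].valid_report.rmse == b["UL"].valid_report.rmse

    def test_training_r2_exceeds_validation_on_average(self):
        """Overfitting direction: across many random partitions the training
        fit explains at least as much variance as the held-out predictions."""
        cfg = GeneratorConfig(seed=31)
        table = generate_cohort(cfg, include_trajectories=False).table
        train_r2, valid_r2 = [], []
        for seed in range(50):
            res = run_ssv(
                table, outcomes=["ELBOW"], seed=seed, select=False, do_balance=False
            )["ELBOW"]
            train_r2.append(res.train_report.r2)
            valid_r2.append(res.valid_report.r2)
        assert np.mean(train_r2) >= np.mean(valid_r2)

    def test_train_scope_standardizer_uses_training_statistics(self, cohort_table):
        res = run_ssv(
            cohort_table, outcomes=["UL"], seed=1, do_balance=False,
            standardize_scope="train",
        )["UL"]
        train_rows = cohort_table[cohort_table["id"].isin(res.split.train_ids)]
        assert res.standardizer.means["mpe_c"] == pytest.approx(
            train_rows["mpe_c"].mean()
        )


class TestRunLoocv:
    def test_performs_one_fit_per_record(self, cohort_table):
        res = run_loocv(cohort_table, outcomes=["ELBOW"])
        assert res["ELBOW"].n_fits == len(cohort_table)

    def test_noiseless_predictions_equal_truth(self, linear_table):
        res = run_loocv(linear_table, outcomes=["UL"], select=False)
        np.testing.assert_allclose(
            res["UL"].oof_predictions, linear_table["mi_ul_t2"], atol=1e-8
        )

    def test_matches_hat_matrix_identity(self, cohort_table):
        """Independent oracle: for a fixed design, the out-of-fold residual
        equals e_i / (1 - h_ii) from the single full fit."""
        res = run_loocv(cohort_table, outcomes=["UL"], select=False)["UL"]
        df = cohort_table.copy()
        df["sex_male"] = (df["sex"] == "male").astype(float)
        sdf = Standardizer().fit_transform(df)
        y, X = design_matrix(sdf, "UL")
        Xc = np.column_stack([np.ones(len(X)), X.to_numpy()])
        H = Xc @ np.linalg.solve(Xc.T @ Xc, Xc.T)
        e_full = y - H @ y
        loo_resid = e_full / (1 - np.diag(H))
        np.testing.assert_allclose(
            y - res.oof_predictions.to_numpy(), loo_resid, atol=1e-8
        )

    def test_small_cohorts_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            run_loocv(pd.DataFrame({"id": ["a", "b"]}))

    def test_final_model_keeps_generating_predictor(self, cohort_table):
        res = run_loocv(cohort_table, outcomes=["UL"])["UL"]
        assert "mpe_c" in res.final_model.predictors


class TestPredictPublished:
    @pytest.mark.parametrize(
        "outcome, z, expected",
        [
            ("ELBOW", 0.0, 12.99),
            ("SHOULDER", 0.0, 13.70),
            ("UL", 0.0, 32.50),
            ("UL", 1.0, 20.51),
        ],
    )
    def test_published_equations(self, outcome, z, expected):
        assert predict_published(outcome, z) == pytest.approx(expected)

    def test_unknown_outcome_rejected(self):
        with pytest.raises(KeyError):
            predict_published("WRIST", 0.0)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            predict_published("UL", float("inf"))
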