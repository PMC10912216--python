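"""Rank statistics (AS 89, partial Spearman) and patient-model adaptation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hgfdyn.cohort import (adapt_to_patients, correlation_table,
                           partial_spearman, patient_features, rank_patients,
                           significance_stars, spearman_test)
from hgfdyn.synth import default_ground_truth, gen_patient_cohort


def exact_two_sided_p(x, y):
    """Independent oracle: full permutation enumeration of the null."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1.0
    ry = np.argsort(np.argsort(y)) + 1.0
    s_obs = np.sum((rx - ry) ** 2)
    mean_s = n * (n * n - 1) / 6.0
    count = 0
    total = 0
    for perm in itertools.permutations(range(1, n + 1)):
        s = np.sum((rx - np.array(perm)) ** 2)
        if abs(s - mean_s) >= abs(s_obs - mean_s) - 1e-9:
            count += 1
        total += 1
    return count / total


class TestSpearmanAS89:
    def test_perfect_monotone(self):
        x = np.arange(7.0)
        rho, p = spearman_test(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        # only the two extreme orderings are as extreme: p = 2/5040
        assert p == pytest.approx(2 / 5040)

    def test_antithetic(self):
        x = np.arange(8.0)
        rho, _ = spearman_test(x, -x)
        assert rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("y", [
        [2, 1, 3, 4, 5, 7, 6],
        [4, 2, 6, 1, 7, 3, 5],
        [6, 7, 4, 5, 2, 3, 1],
        [1, 3, 5, 7, 2, 4, 6],
    ])
    def test_n7_matches_permutation_enumeration(self, y):
        x = np.arange(1.0, 8.0)
        rho, p = spearman_test(x, np.asarray(y, dtype=float))
        # the small-n branch is exact: equality with brute-force enumeration
        assert p == pytest.approx(exact_two_sided_p(x, np.asarray(y)), abs=1e-12)

    def test_edgeworth_branch_close_to_exact(self):
        # n = 12 exceeds the exact branch; reference value computed with the
        # exact null distribution (R cor.test exact=TRUE): p = 0.066629
        x = np.arange(1.0, 13.0)
        y = np.array([5, 3, 1, 8, 2, 12, 7, 4, 11, 6, 10, 9], dtype=float)
        rho, p = spearman_test(x, y)
        assert rho == pytest.approx(0.552448, abs=1e-6)
        assert p == pytest.approx(0.066629, abs=0.01)

    def test_ties_fall_back_to_t_approximation(self):
        # reference value from R cor.test with tied data (t approximation)
        x = np.array([1, 2, 2, 4, 5, 6, 7], dtype=float)
        y = np.array([2, 1, 4, 3, 6, 5, 7], dtype=float)
        rho, p = spearman_test(x, y)
        assert rho == pytest.approx(0.846881, abs=1e-6)
        assert p == pytest.approx(0.01619713, abs=1e-7)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError):
            spearman_test(np.ones(6), np.arange(6.0))

    def test_too_short(self):
        with pytest.raises(ValueError):
            spearman_test([1, 2, 3], [3, 2, 1])


class TestPartialSpearman:
    def test_zero_confounders_equals_spearman_rho(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        rho0, _ = spearman_test(x, y)
        rho, _ = partial_spearman(x, y, np.empty((30, 0)))
        assert rho == pytest.approx(rho0, abs=1e-12)

    def test_trivariate_gaussian_matches_closed_form(self):
        rng = np.random.default_rng(1)
        n = 10_000
        z = rng.standard_normal(n)
        x = 0.7 * z + 0.7 * rng.standard_normal(n)
        y = 0.5 * z + 0.9 * rng.standard_normal(n)
        rho, _ = partial_spearman(x, y, z.reshape(-1, 1))
        from scipy.stats import rankdata
        rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
        rxy = np.corrcoef(rx, ry)[0, 1]
        rxz = np.corrcoef(rx, rz)[0, 1]
        ryz = np.corrcoef(ry, rz)[0, 1]
        closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert rho == pytest.approx(closed, abs=0.02)

    def test_linear_function_of_confounder_partials_out(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(50)
        x = rng.standard_normal(50)
        y = 3.0 * z + 1.0  # y is exactly a function of the confounder
        rho, p = partial_spearman(x, y, z.reshape(-1, 1))
        assert abs(rho) < 0.15

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.standard_normal(40),
                           "y": rng.standard_normal(40),
                           "z": rng.standard_normal(40)})
        res = pingouin.partial_corr(df, x="x", y="y", covar=["z"],
                                    method="spearman")
        rho, p = partial_spearman(df["x"], df["y"], df[["z"]].to_numpy())
        assert rho == pytest.approx(float(res["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(res["p_val"].iloc[0]), abs=1e-10)

    def test_singular_confounders_rejected(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(20)
        Z = np.column_stack([z, z])
        with pytest.raises(ValueError):
            partial_spearman(rng.standard_normal(20), rng.standard_normal(20), Z)

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            partial_spearman([1, 2, 3, 4], [4, 3, 2, 1], np.ones((4, 2)))


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.0005, "***"), (0.001, "**"), (0.005, "**"), (0.01, "*"),
        (0.049, "*"), (0.05, ""), (0.5, ""),
    ])
    def test_boundaries(self, p, expected):
        assert significance_stars(p) == expected


class TestRankPatients:
    def test_descending_by_kbasal_with_id_tiebreak(self):
        feats = pd.DataFrame({"patient": ["P3", "P1", "P2"],
                              "k_basal": [1.0, 2.0, 1.0]})
        assert rank_patients(feats) == ["P1", "P2", "P3"]

    def test_singleton(self):
        feats = pd.DataFrame({"patient": ["P1"], "k_basal": [0.5]})
        assert rank_patients(feats) == ["P1"]

    def test_missing_feature(self):
        feats = pd.DataFrame({"patient": ["P1"], "k_basal": [np.nan]})
        with pytest.raises(ValueError):
            rank_patients(feats)


@pytest.fixture(scope="module")
def cohort_fit():
    data = gen_patient_cohort(7, seed=5)
    mouse = default_ground_truth().sd_params().native()
    pfit = adapt_to_patients(mouse, data, seed=1, n_starts=4)
    return data, pfit, patient_features(pfit)


class TestPatientAdaptation:
    def test_recovered_kbasal_rank_order_matches_truth(self, cohort_fit):
        data, pfit, feats = cohort_fit
        true_kb = data.truth.set_index("patient")["k_basal_MET"]
        est_kb = feats.set_index("patient")["k_basal"]
        rho, _ = spearman_test(true_kb[est_kb.index], est_kb)
        assert rho == pytest.approx(1.0)

    def test_features_monotone_in_generating_kbasal(self, cohort_fit):
        data, pfit, feats = cohort_fit
        merged = feats.merge(data.truth, on="patient")
        rho, p = spearman_test(merged["k_basal_MET"], merged["k_basal"])
        assert rho > 0.9

    def test_outcome_correlation_recovered(self, cohort_fit):
        data, pfit, feats = cohort_fit
        outcomes = ["complication_index", "hospitalization_days"]
        tab = correlation_table(feats, data.clinical,
                                feature_cols=["k_basal"],
                                clinical_cols=outcomes,
                                outcome_cols=outcomes)
        assert (tab["rho"] > 0).all()
        assert (tab["p"] < 0.05).any()
        assert {"partial_rho", "partial_p"} <= set(tab.columns)

    def test_ratio_features_consistent(self, cohort_fit):
        _, _, feats = cohort_fit
        assert np.allclose(feats["k_basal_over_k_total_met"],
                           feats["k_basal"] / feats["k_total_met"])
        assert np.allclose(feats["k_basal_over_auc_ppakt"],
                           feats["k_basal"] / feats["auc_ppakt"])

    def test_empty_free_subset_returns_mouse_unchanged(self):
        data = gen_patient_cohort(3, seed=0)
        mouse = default_ground_truth().sd_params().native()
        # also freeze the human-shared kinetics: nothing to estimate
        import hgfdyn.cohort as cohort_mod
        pfit = adapt_to_patients(mouse, data, free_specific=[])
        # only the human-shared parameters remain free in this configuration
        assert set(pfit.fit.free) <= set(cohort_mod.HUMAN_SHARED)
        p = pfit.patient_params("P01")
        for name, v in mouse.items():
            if name not in cohort_mod.HUMAN_SHARED:
                assert p[name] == v

    def test_missing_basal_measurement_flagged(self):
        data = gen_patient_cohort(3, seed=0)
        tc = data.timecourses
        data.timecourses = tc[~((tc["patient"] == "P01") & (tc["dose"] == 0))]
        mouse = default_ground_truth().sd_params().native()
        with pytest.raises(ValueError, match="P01"):
            adapt_to_patients(mouse, data)
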