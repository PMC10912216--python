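"""Objective, multi-start optimization, profiles and BIC on small problems."""

import numpy as np
import pandas as pd
import pytest

from hgfdyn.estimate import (FitProblem, bic, compare_hypotheses,
                             multistart_fit, negloglik, profile_likelihood)
from hgfdyn.observe import default_observation_model, observe
from hgfdyn.simulate import reference_network_packed, simulate


def observable_table(params, dose, times, targets, sigma_rel=0.1, rng=None,
                     condition="SD"):
    """Noisy (or exact) data table in FitProblem layout from a simulation."""
    net, packed = reference_network_packed()
    om = default_observation_model()
    traj = simulate(net, params, dose, times, packed=packed)
    obs = observe(traj, om, observables=list(targets))
    vals = obs["value"].to_numpy().copy()
    if rng is not None:
        vals = vals * (1.0 + sigma_rel * rng.standard_normal(len(vals)))
    return pd.DataFrame({
        "target": obs["observable"], "condition": condition, "dose": dose,
        "time": obs["time"], "value": vals,
        "sigma": np.maximum(sigma_rel * vals, 1e-9),
    })


@pytest.fixture(scope="module")
def exact_problem(truth):
    """Data equal to the model prediction; one free scale parameter."""
    times = np.linspace(0.0, 240.0, 9)
    data = observable_table(truth.sd_params(), 40.0, times, ["pMET"])
    return FitProblem(data=data, base=truth.sd_params().native(),
                      free=["scale_pMET"], bounds={"scale_pMET": (-2, 2)},
                      conditions={"SD": 40.0})


class TestNegLogLik:
    def test_zero_at_exact_prediction(self, exact_problem):
        assert negloglik(exact_problem, np.array([0.0])) == pytest.approx(0.0, abs=1e-12)

    def test_one_point_one_sigma_off_gives_one(self, truth):
        times = np.linspace(0.0, 240.0, 5)
        data = observable_table(truth.sd_params(), 40.0, times, ["pMET"])
        data.loc[2, "value"] += data.loc[2, "sigma"]
        prob = FitProblem(data=data, base=truth.sd_params().native(),
                          free=["scale_pMET"], bounds={"scale_pMET": (-2, 2)},
                          conditions={"SD": 40.0})
        assert negloglik(prob, np.array([0.0])) == pytest.approx(1.0, rel=1e-7)

    def test_matches_independent_residual_sum(self, truth):
        # brute-force oracle: recompute the weighted sum from scratch
        rng = np.random.default_rng(3)
        times = np.linspace(0.0, 240.0, 7)
        data = observable_table(truth.sd_params(), 40.0, times,
                                ["pMET", "pERK"], rng=rng)
        prob = FitProblem(data=data, base=truth.sd_params().native(),
                          free=["scale_pMET", "scale_pERK"],
                          bounds={"scale_pMET": (-2, 2), "scale_pERK": (-2, 2)},
                          conditions={"SD": 40.0})
        theta = np.array([0.05, -0.1])
        net, packed = reference_network_packed()
        om = default_observation_model()
        traj = simulate(net, truth.sd_params(), 40.0, times, packed=packed)
        total = 0.0
        for _, row in data.iterrows():
            states = om.mapping[row["target"]]
            model = sum(traj.state(s)[list(times).index(row["time"])]
                        for s in states)
            scale = 10.0 ** theta[0 if row["target"] == "pMET" else 1]
            total += ((scale * model - row["value"]) / row["sigma"]) ** 2
        assert negloglik(prob, theta) == pytest.approx(total, rel=1e-9)

    def test_out_of_bounds_rejected(self, exact_problem):
        with pytest.raises(ValueError):
            negloglik(exact_problem, np.array([5.0]))


class TestMultistart:
    def test_linear_scale_problem_recovers_exact_optimum(self, truth):
        # observable linear in the free scale: optimizer must hit the weighted
        # least-squares optimum computed in closed form
        rng = np.random.default_rng(5)
        times = np.linspace(0.0, 240.0, 9)
        data = observable_table(truth.sd_params(), 40.0, times, ["pMET"],
                                rng=rng)
        prob = FitProblem(data=data, base=truth.sd_params().native(),
                          free=["scale_pMET"], bounds={"scale_pMET": (-2, 2)},
                          conditions={"SD": 40.0})
        fit = multistart_fit(prob, n_starts=3, seed=0, max_nfev=200)
        net, packed = reference_network_packed()
        traj = simulate(net, truth.sd_params(), 40.0, times, packed=packed)
        model = traj.state("pMET")
        w = 1.0 / data["sigma"].to_numpy() ** 2
        y = data["value"].to_numpy()
        closed = np.sum(w * model * y) / np.sum(w * model * model)
        assert 10.0 ** fit.best_params[0] == pytest.approx(closed, rel=1e-6)

    def test_same_seed_bit_identical_waterfall(self, exact_problem):
        f1 = multistart_fit(exact_problem, n_starts=4, seed=11, max_nfev=50)
        f2 = multistart_fit(exact_problem, n_starts=4, seed=11, max_nfev=50)
        assert np.array_equal(f1.waterfall, f2.waterfall)
        assert np.array_equal(f1.best_params, f2.best_params)

    def test_waterfall_sorted_and_best_first(self, exact_problem):
        fit = multistart_fit(exact_problem, n_starts=5, seed=2, max_nfev=50)
        assert np.all(np.diff(fit.waterfall) >= 0)
        assert fit.best_objective == fit.waterfall[0]
        assert 0 < fit.convergence_fraction <= 1

    def test_invalid_start_count(self, exact_problem):
        with pytest.raises(ValueError):
            multistart_fit(exact_problem, n_starts=0)


class TestProfile:
    def test_gaussian_problem_ci_matches_closed_form(self, truth):
        # a single linear scale parameter: profile CI must equal the analytic
        # 95% interval of the weighted linear regression
        rng = np.random.default_rng(8)
        times = np.linspace(0.0, 240.0, 13)
        data = observable_table(truth.sd_params(), 40.0, times, ["pMET"],
                                sigma_rel=0.1, rng=rng)
        prob = FitProblem(data=data, base=truth.sd_params().native(),
                          free=["scale_pMET"], bounds={"scale_pMET": (-2, 2)},
                          conditions={"SD": 40.0})
        fit = multistart_fit(prob, n_starts=3, seed=0, max_nfev=200)
        profile = profile_likelihood(prob, fit, "scale_pMET",
                                     init_step=0.002)
        net, packed = reference_network_packed()
        model = simulate(net, truth.sd_params(), 40.0, times,
                         packed=packed).state("pMET")
        w = 1.0 / data["sigma"].to_numpy() ** 2
        c_hat = np.sum(w * model * data["value"]) / np.sum(w * model * model)
        se = 1.0 / np.sqrt(np.sum(w * model * model))
        lo, hi = profile.ci_native()
        assert lo == pytest.approx(c_hat - 1.959964 * se, rel=2e-3)
        assert hi == pytest.approx(c_hat + 1.959964 * se, rel=2e-3)

    def test_structural_nonidentifiability_flat_profile(self, truth):
        # abundance x scale degeneracy: only the product enters the likelihood
        rng = np.random.default_rng(9)
        times = np.linspace(0.0, 240.0, 9)
        data = observable_table(truth.sd_params(), 40.0, times, ["pS6"],
                                rng=rng)
        base = truth.sd_params().native()
        c = np.log10(base["k_total_S6"])
        prob = FitProblem(data=data, base=base,
                          free=["k_total_S6@SD", "scale_pS6"],
                          bounds={"k_total_S6@SD": (c - 1, c + 1),
                                  "scale_pS6": (-3, 3)},
                          conditions={"SD": 40.0})
        fit = multistart_fit(prob, n_starts=4, seed=1, max_nfev=300)
        profile = profile_likelihood(prob, fit, "k_total_S6@SD")
        assert profile.lower_open and profile.upper_open
        assert not profile.identifiable
        span = profile.objective.max() - profile.objective.min()
        assert span < 0.5  # flat within the fitted noise scale

    def test_profile_minimum_not_below_global_optimum(self, exact_problem):
        fit = multistart_fit(exact_problem, n_starts=3, seed=0, max_nfev=100)
        profile = profile_likelihood(exact_problem, fit, "scale_pMET")
        assert profile.objective.min() >= fit.best_objective - 1e-6


class TestBic:
    def test_closed_form_difference(self):
        assert bic(10.0, 100, 6) - bic(10.0, 100, 5) == pytest.approx(np.log(100))

    def test_smaller_model_wins_at_equal_fit(self):
        assert bic(50.0, 80, 5) < bic(50.0, 80, 7)

    def test_linear_gaussian_matches_hand_computed(self):
        # chi2 objective of a hand-made linear fit, BIC assembled manually
        rng = np.random.default_rng(12)
        x = np.linspace(0, 1, 20)
        y = 2.0 * x + rng.normal(0, 0.1, 20)
        coef = np.sum(x * y) / np.sum(x * x)
        chi2 = float(np.sum(((y - coef * x) / 0.1) ** 2))
        assert bic(chi2, 20, 1) == pytest.approx(chi2 + np.log(20))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            bic(1.0, 0, 1)


class TestCompareHypotheses:
    def test_duplicated_hypothesis_ties_and_extra_parameter_penalized(self, truth):
        times = np.linspace(0.0, 240.0, 7)
        data = observable_table(truth.sd_params(), 40.0, times, ["pMET"])
        base = truth.sd_params().native()

        def make(free):
            bounds = {}
            for f in free:
                bounds[f] = (-2, 2) if f.startswith("scale") else (
                    np.log10(base[f.split("@")[0]]) - 1,
                    np.log10(base[f.split("@")[0]]) + 1)
            return FitProblem(data=data.copy(), base=base, free=free,
                              bounds=bounds, conditions={"SD": 40.0})

        probs = {
            "a": make(["scale_pMET"]),
            "a_again": make(["scale_pMET"]),
            "with_unused": make(["scale_pMET", "k_total_S6@SD"]),
        }
        table = compare_hypotheses(probs, n_starts=2, seed=0, max_nfev=200)
        row = table.set_index("hypothesis")
        assert row.loc["a", "bic"] == pytest.approx(row.loc["a_again", "bic"])
        # k_total_S6 does not influence pMET: fit unchanged, BIC strictly worse
        assert row.loc["with_unused", "objective"] == pytest.approx(
            row.loc["a", "objective"], abs=0.05)
        assert row.loc["with_unused", "bic"] > row.loc["a", "bic"]

    def test_non_shared_data_rejected(self, truth):
        times = np.linspace(0.0, 240.0, 5)
        d1 = observable_table(truth.sd_params(), 40.0, times, ["pMET"])
        d2 = d1.copy()
        d2.loc[0, "value"] *= 2
        base = truth.sd_params().native()
        p1 = FitProblem(data=d1, base=base, free=["scale_pMET"],
                        bounds={"scale_pMET": (-2, 2)}, conditions={"SD": 40.0})
        p2 = FitProblem(data=d2, base=base, free=["scale_pMET"],
                        bounds={"scale_pMET": (-2, 2)}, conditions={"SD": 40.0})
        with pytest.raises(ValueError):
            compare_hypotheses({"a": p1, "b": p2}, n_starts=1)
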