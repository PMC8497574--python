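import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from steppesim.inference import (
    SCENARIO_COL,
    abc_posterior,
    add_migrant_numbers,
    bayes_factor_label,
    cross_validate,
    gof_pvalue,
    hdi,
    model_choice,
    posterior_summaries,
    prediction_error,
)


def _table(rng, n, scenario="s", stats=None, params=None):
    df = pd.DataFrame({SCENARIO_COL: [scenario] * n})
    params = params or {}
    for name, vals in params.items():
        df[name] = vals
    stats = stats if stats is not None else rng.normal(size=(n, 3))
    for j in range(stats.shape[1]):
        df[f"stat_{j}"] = stats[:, j]
    return df


class TestAbcPosterior:
    def test_tolerance_one_retains_all(self):
        rng = np.random.default_rng(0)
        tab = _table(rng, 200, params={"theta": rng.uniform(size=200)})
        post = abc_posterior(tab, np.zeros(3), tolerance=1.0, method="rejection",
                             param_cols=["theta"])
        assert len(post.params) == 200

    def test_exact_match_retained_at_distance_zero(self):
        rng = np.random.default_rng(1)
        stats = rng.normal(size=(100, 3))
        tab = _table(rng, 100, stats=stats, params={"theta": np.arange(100.0)})
        post = abc_posterior(tab, stats[17], tolerance=0.1, method="rejection",
                             param_cols=["theta"])
        assert post.distances.min() == 0.0
        assert 17.0 in post.params["theta"].to_numpy()

    def test_linear_map_collapses_to_truth(self):
        """With a noiseless linear map θ→stats the local-linear adjustment
        recovers the generating parameters exactly (linear-algebra oracle)."""
        rng = np.random.default_rng(2)
        theta = rng.uniform(-1, 1, size=(400, 2))
        A = rng.normal(size=(2, 5))
        stats = theta @ A + 3.0
        truth = np.array([0.21, -0.4])
        tab = _table(rng, 400, stats=stats,
                     params={"t0": theta[:, 0], "t1": theta[:, 1]})
        post = abc_posterior(tab, truth @ A + 3.0, tolerance=0.2,
                             method="loclinear", param_cols=["t0", "t1"],
                             bounds={})
        for j, name in enumerate(["t0", "t1"]):
            assert np.abs(post.params[name] - truth[j]).max() < 1e-6

    def test_tolerance_and_retention_errors(self):
        rng = np.random.default_rng(3)
        tab = _table(rng, 50, params={"theta": np.ones(50)})
        with pytest.raises(ValueError):
            abc_posterior(tab, np.zeros(3), tolerance=0.0)
        with pytest.raises(ValueError, match="retained"):
            abc_posterior(tab, np.zeros(3), tolerance=0.01, param_cols=["theta"])

    def test_tolerance_one_rejection_returns_prior(self):
        rng = np.random.default_rng(4)
        prior = rng.uniform(size=10_000)
        tab = _table(rng, 10_000, params={"theta": prior})
        post = abc_posterior(tab, np.zeros(3), tolerance=1.0, method="rejection",
                             param_cols=["theta"])
        assert kstest(post.params["theta"], "uniform").statistic < 0.05


class TestModelChoice:
    def test_single_scenario_probability_one(self):
        rng = np.random.default_rng(0)
        probs = model_choice(_table(rng, 300), np.zeros(3), tolerance=0.1)
        assert probs.to_dict() == {"s": 1.0}

    def test_identical_distributions_split_evenly(self):
        rng = np.random.default_rng(1)
        tab = pd.concat([_table(rng, 2000, scenario="a"),
                         _table(rng, 2000, scenario="b")], ignore_index=True)
        probs = model_choice(tab, np.zeros(3), tolerance=0.05)
        se = 0.5 / np.sqrt(0.05 * 4000)
        assert abs(probs["a"] - 0.5) < 3 * se

    def test_disjoint_supports_are_separated(self):
        rng = np.random.default_rng(2)
        tab = pd.concat([
            _table(rng, 500, scenario="near", stats=rng.normal(0, 0.5, (500, 3))),
            _table(rng, 500, scenario="far", stats=rng.normal(50, 0.5, (500, 3))),
        ], ignore_index=True)
        probs = model_choice(tab, np.zeros(3), tolerance=0.05)
        assert probs["near"] > 0.99 and probs["far"] < 0.01

    def test_invariant_to_uniform_duplication(self):
        rng = np.random.default_rng(3)
        tab = pd.concat([_table(rng, 400, scenario="a"),
                         _table(rng, 400, scenario="b",
                                stats=rng.normal(1, 1, (400, 3)))],
                        ignore_index=True)
        obs = np.zeros(3)
        p1 = model_choice(tab, obs, tolerance=0.1)
        p2 = model_choice(pd.concat([tab, tab], ignore_index=True), obs, tolerance=0.1)
        assert np.allclose(p1.to_numpy(), p2.to_numpy(), atol=0.02)
        assert p1.sum() == pytest.approx(1.0)


class TestGofPvalue:
    def test_central_vs_outlying_observation(self):
        rng = np.random.default_rng(0)
        tab = _table(rng, 800, stats=rng.normal(size=(800, 10)))
        central = np.median(tab.filter(like="stat_").to_numpy(), axis=0)
        assert gof_pvalue(tab, central, rng=np.random.default_rng(1)) > 0.5
        assert gof_pvalue(tab, np.full(10, 25.0), rng=np.random.default_rng(1)) < 0.05

    def test_minimum_rows_enforced(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            gof_pvalue(_table(rng, 50), np.zeros(3))


class TestBayesFactorLabel:
    @pytest.mark.parametrize("bf,label", [
        (10.22, "strong"),      # no-competition vs competition block
        (1.98, "anecdotal"),    # weakest pairwise support
        (371.16, "extreme"),    # strongest pairwise support
        (5.59, "moderate"),
        (26.61, "strong"),
        (45.0, "very strong"),
    ])
    def test_verbal_scale(self, bf, label):
        out = bayes_factor_label(bf, 1.0)
        assert out.value == pytest.approx(bf)
        assert out.label == label

    def test_reciprocal_uses_same_magnitude_scale(self):
        assert bayes_factor_label(1.0, 20.0).label == "strong"

    def test_zero_denominator_flagged_not_raised(self):
        out = bayes_factor_label(0.5, 0.0)
        assert out.infinite and out.label == "extreme" and np.isinf(out.value)

    def test_zero_numerator_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor_label(0.0, 0.5)


class TestCrossValidate:
    def test_separable_scenarios_recovered_perfectly(self):
        rng = np.random.default_rng(0)
        tab = pd.concat([
            _table(rng, 150, scenario="a", stats=rng.normal(0, 0.3, (150, 3)),
                   params={"gamma": rng.uniform(0.001, 0.029, 150)}),
            _table(rng, 150, scenario="b", stats=rng.normal(30, 0.3, (150, 3)),
                   params={"gamma": rng.uniform(0.001, 0.029, 150)}),
        ], ignore_index=True)
        cv = cross_validate(tab, n_replicates=10, tolerance=0.1,
                            rng=np.random.default_rng(1), param_cols=["gamma"])
        assert np.allclose(cv.confusion.to_numpy(), np.eye(2))
        assert np.allclose(cv.recovery.to_numpy(), [2.0, 2.0])  # PR = 1/P(sel)=...
        assert (cv.prediction_errors.to_numpy() >= 0).all()

    def test_replicate_minimum(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            cross_validate(_table(rng, 100), n_replicates=1)


class TestPredictionError:
    def test_perfect_estimator_zero(self):
        th = np.linspace(0, 1, 40)
        assert prediction_error(th, th) == 0.0

    def test_constant_mean_estimator_identity(self):
        """θ̃ = mean(θ) gives PE = n−1 by the identity Σ(θ̄−θ)² = (n−1)·Var."""
        rng = np.random.default_rng(0)
        th = rng.normal(size=100)
        est = np.full(100, th.mean())
        assert prediction_error(est, th) == pytest.approx(99.0)
        assert prediction_error(est, th, normalized=True) == pytest.approx(0.99)


class TestPosteriorSummaries:
    def test_point_mass(self):
        out = posterior_summaries(np.full(50, 3.25))
        row = out.loc["param"]
        assert row["mean"] == row["median"] == row["mode"] == 3.25
        assert row["hdi_low"] == row["hdi_high"] == 3.25

    def test_symmetric_unimodal_hdi(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20_000)
        out = posterior_summaries(x).loc["param"]
        assert out["hdi_low"] == pytest.approx(-out["hdi_high"], abs=0.1)
        assert out["hdi_high"] == pytest.approx(norm.ppf(0.95), abs=0.1)

    def test_mixture_hdi_mass_calibrated(self):
        """HDI holds 0.90 ± 0.02 of the draws, matching a quantile-grid oracle
        on the analytic two-component normal mixture."""
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-2, 0.5, 5000), rng.normal(2, 0.5, 5000)])
        lo, hi = hdi(x, mass=0.9)
        assert np.mean((x >= lo) & (x <= hi)) == pytest.approx(0.9, abs=0.02)
        # oracle: shortest interval on a fine grid of the analytic density
        grid = np.linspace(-5, 5, 4001)
        cdf = 0.5 * norm.cdf(grid, -2, 0.5) + 0.5 * norm.cdf(grid, 2, 0.5)
        best = (None, np.inf)
        for i in range(0, 4001, 10):
            j = np.searchsorted(cdf, cdf[i] + 0.9)
            if j < 4001 and grid[j] - grid[i] < best[1]:
                best = (i, grid[j] - grid[i])
        assert hi - lo == pytest.approx(best[1], abs=0.15)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            posterior_summaries(np.array([1.0, 2.0]), weights=np.zeros(2))

    def test_weighted_hdi_concentrates_on_heavy_draws(self):
        x = np.concatenate([np.linspace(0, 1, 100), np.linspace(10, 11, 100)])
        w = np.concatenate([np.full(100, 1.0), np.full(100, 1e-6)])
        lo, hi = hdi(x, mass=0.9, weights=w)
        assert hi <= 1.0


def test_add_migrant_numbers():
    df = pd.DataFrame({"K_F": [5000.0], "m_F": [0.6], "K_P": [2000.0], "m_P": [0.5]})
    out = add_migrant_numbers(df)
    assert out.loc[0, "Nm_F"] == 3000.0 and out.loc[0, "Nm_P"] == 1000.0
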