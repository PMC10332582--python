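"""Single-species occupancy likelihood, ML and MCMC engines."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from camtrapocc.covariates import build_design
from camtrapocc.occupancy import (OccuModelSpec, OccuParams, compute_rhat,
                                  conditional_occupancy, fit_bayes, fit_ml,
                                  predict_response, site_likelihood)
from camtrapocc.simulate import SimScenario, simulate_single


def intercept_design(n, J):
    table = pd.DataFrame({"station_id": [f"S{i}" for i in range(n)]})
    return build_design(table, [], [], n_occasions=J)


class TestSiteLikelihood:
    @pytest.mark.parametrize("history,expected", [
        ([1, 0, 1], 0.0625),            # psi * p(1-p)p
        ([0, 0, 0], 0.5625),            # psi (1-p)^3 + (1-psi)
        ([1, np.nan, 0], 0.125),        # missing occasion skipped
    ])
    def test_hand_computed_values(self, history, expected):
        assert site_likelihood(history, 0.5, 0.5) == pytest.approx(expected)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="no observed"):
            site_likelihood([np.nan, np.nan], 0.5, 0.5)

    @pytest.mark.parametrize("J", [1, 2, 3, 4])
    def test_normalization_over_all_histories(self, J):
        """Sum over the 2^J possible histories is exactly 1."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            psi, p = rng.uniform(0.01, 0.99, 2)
            total = sum(site_likelihood(h, psi, p)
                        for h in itertools.product([0, 1], repeat=J))
            assert total == pytest.approx(1.0, abs=1e-10)


class TestFitML:
    def test_all_detected_hits_boundary(self):
        from camtrapocc.survey import DetectionHistory
        m = np.ones((10, 4))
        hist = DetectionHistory("x", [f"S{i}" for i in range(10)], m,
                                np.full((10, 4), 7))
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_ml(hist, intercept_design(10, 4))
        psi_hat = expit(fit.params.beta[0])
        p_hat = expit(fit.params.alpha[0])
        assert psi_hat > 0.999 and p_hat > 0.999

    def test_no_detections_errors(self):
        from camtrapocc.survey import DetectionHistory
        m = np.zeros((10, 4))
        hist = DetectionHistory("x", [f"S{i}" for i in range(10)], m,
                                np.full((10, 4), 7))
        with pytest.raises(ValueError, match="identifiable"):
            fit_ml(hist, intercept_design(10, 4))

    def test_grid_oracle_intercept_only(self):
        """MLE agrees with a brute-force (psi, p) grid to 1e-3."""
        h, _, _ = simulate_single(SimScenario(n_sites=20, n_occasions=5,
                                              psi=0.6, p=0.4, seed=5))
        fit = fit_ml(h, intercept_design(20, 5))
        grid = np.arange(0.001, 1.0, 0.001)
        d = np.nansum(h.matrix, axis=1)
        J = (~np.isnan(h.matrix)).sum(axis=1)
        best, best_ll = None, -np.inf
        PSI, P = np.meshgrid(grid, grid, indexing="ij")
        ll = np.zeros_like(PSI)
        for di, Ji in zip(d, J):
            site = PSI * P ** di * (1 - P) ** (Ji - di)
            if di == 0:
                site = site + (1 - PSI)
            ll += np.log(site)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert expit(fit.params.beta[0]) == pytest.approx(grid[i], abs=1e-3)
        assert expit(fit.params.alpha[0]) == pytest.approx(grid[j], abs=1e-3)

    def test_parameter_recovery_large_n(self):
        h, _, _ = simulate_single(SimScenario(n_sites=500, n_occasions=19,
                                              psi=0.6, p=0.3, seed=17))
        fit = fit_ml(h, intercept_design(500, 19))
        assert expit(fit.params.beta[0]) == pytest.approx(0.6, abs=0.05)
        assert expit(fit.params.alpha[0]) == pytest.approx(0.3, abs=0.05)

    def test_pointwise_sums_to_loglik(self):
        h, _, _ = simulate_single(SimScenario(n_sites=50, n_occasions=6,
                                              psi=0.5, p=0.3, seed=2))
        fit = fit_ml(h, intercept_design(50, 6))
        assert fit.pointwise.sum() == pytest.approx(fit.loglik, abs=1e-8)
        assert fit.n_params == 2

    def test_report_carries_interpretation_labels(self):
        h, _, _ = simulate_single(SimScenario(n_sites=50, n_occasions=6,
                                              psi=0.5, p=0.3, seed=2))
        rep = fit_ml(h, intercept_design(50, 6)).to_report()
        assert rep["interpretation"]["psi"] == "habitat use"
        assert rep["interpretation"]["p"] == "intensity of use"


class TestConditionalOccupancy:
    def test_detected_site_is_certain(self):
        h, _, _ = simulate_single(SimScenario(n_sites=50, n_occasions=6,
                                              psi=0.5, p=0.4, seed=3))
        fit = fit_ml(h, intercept_design(50, 6))
        co = conditional_occupancy(fit)
        detected = np.nansum(h.matrix, axis=1) > 0
        np.testing.assert_array_equal(co[detected], 1.0)
        assert (co >= 0).all() and (co <= 1).all()

    def test_bayes_rule_hand_value(self):
        # all-zero J=3 site, psi = p = 0.5: 0.0625 / 0.5625
        psi = p = 0.5
        num = psi * (1 - p) ** 3
        assert num / (num + 1 - psi) == pytest.approx(1.0 / 9.0)

    def test_high_p_drives_conditional_to_zero(self):
        y = np.zeros(3)
        num = 0.5 * (1 - 0.999) ** 3
        assert num / (num + 0.5) < 1e-8


class TestComputeRhat:
    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(10)
        draws = rng.standard_normal((3, 5000))
        assert compute_rhat(draws) < 1.01

    def test_nonmixed_chains_flagged(self):
        rng = np.random.default_rng(11)
        draws = np.stack([rng.normal(0, 1, 2000), rng.normal(10, 1, 2000)])
        assert compute_rhat(draws) > 1.1

    def test_duplicated_chain_is_exactly_one(self):
        rng = np.random.default_rng(12)
        chain = rng.standard_normal(4000)
        draws = np.stack([chain, chain])
        assert compute_rhat(draws, split=False) == pytest.approx(1.0, abs=1e-6)

    def test_matches_arviz_split_rhat(self):
        import arviz as az
        rng = np.random.default_rng(13)
        draws = rng.standard_normal((3, 1000)) + np.array([[0.0], [0.3], [0.6]])
        ours = compute_rhat(draws)
        theirs = float(az.rhat(az.convert_to_dataset(draws[:, :, None]),
                               method="split")["x"].values[0])
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero within-chain"):
            compute_rhat(np.ones((2, 100)))


@pytest.fixture(scope="module")
def sim_fit():
    h, _, truth = simulate_single(SimScenario(n_sites=500, n_occasions=10,
                                              psi=0.6, p=0.3, seed=21))
    designs = intercept_design(500, 10)
    bayes = fit_bayes(h, designs, OccuModelSpec(), chains=3,
                      iterations=6000, seed=77)
    ml = fit_ml(h, designs, OccuModelSpec())
    return bayes, ml


@pytest.fixture(scope="module")
def quad_fit():
    sc = SimScenario(n_sites=400, n_occasions=10,
                     beta=[0.5, 0.4, -0.8], alpha=[-0.5],
                     psi_terms=["elev", "elev^2"], seed=31)
    h, table, _ = simulate_single(sc)
    designs = build_design(table, ["elev", "elev^2"], [], n_occasions=10)
    return fit_ml(h, designs, OccuModelSpec(["elev", "elev^2"], []))


class TestFitBayes:
    def test_seed_determinism(self):
        h, _, _ = simulate_single(SimScenario(n_sites=60, n_occasions=6,
                                              psi=0.6, p=0.3, seed=1))
        d = intercept_design(60, 6)
        f1 = fit_bayes(h, d, iterations=400, seed=5)
        f2 = fit_bayes(h, d, iterations=400, seed=5)
        np.testing.assert_array_equal(f1.draws, f2.draws)

    def test_well_behaved_rhat_below_1_1(self, sim_fit):
        bayes, _ = sim_fit
        assert (bayes.rhat < 1.1).all()
        assert not bayes.convergence_warning

    def test_posterior_agrees_with_ml_at_large_n(self, sim_fit):
        bayes, ml = sim_fit
        post_mean = bayes.summary["mean"].to_numpy()
        post_sd = bayes.summary["sd"].to_numpy()
        np.testing.assert_array_less(np.abs(post_mean - ml.params.pack()),
                                     2 * post_sd)


class TestPredictResponse:
    def test_quadratic_maximum_at_vertex(self, quad_fit):
        b0, b1, b2 = quad_fit.params.beta
        assert b2 < 0
        xstar = -b1 / (2 * b2)
        grid = np.linspace(-3, 3, 601)
        pred = predict_response(quad_fit, "psi", {"elev": grid})
        assert grid[pred["fit"].idxmax()] == pytest.approx(xstar, abs=0.01)

    def test_predictions_inside_unit_interval(self, quad_fit):
        pred = predict_response(quad_fit, "psi",
                                {"elev": np.linspace(-5, 5, 50)})
        assert ((pred > 0) & (pred < 1)).all().all()

    def test_monotone_for_positive_slope(self):
        sc = SimScenario(n_sites=300, n_occasions=8, beta=[0.0, 1.0],
                         alpha=[-0.5], psi_terms=["x"], seed=32)
        h, table, _ = simulate_single(sc)
        designs = build_design(table, ["x"], [], n_occasions=8)
        fit = fit_ml(h, designs, OccuModelSpec(["x"], []))
        assert fit.params.beta[1] > 0
        pred = predict_response(fit, "psi", {"x": np.linspace(-2, 2, 40)})
        assert (np.diff(pred["fit"]) > 0).all()

    def test_unknown_grid_term_errors(self, quad_fit):
        with pytest.raises(ValueError, match="ghost"):
            predict_response(quad_fit, "psi", {"ghost": np.array([0.0])})


class TestWaldCoverage:
    def test_95_interval_covers_truth(self):
        """Over 50 seeded replicates (n=200, J=10), each coefficient's 95%
        Wald interval covers the truth in at least 40."""
        beta_true = np.array([0.4, 0.8])
        alpha_true = np.array([-0.6, 0.5])
        hits = np.zeros(4, dtype=int)
        for seed in range(50):
            sc = SimScenario(n_sites=200, n_occasions=10, beta=beta_true,
                             alpha=alpha_true, psi_terms=["x"], p_terms=["w"],
                             seed=1000 + seed)
            h, table, _ = simulate_single(sc)
            designs = build_design(table, ["x"], ["w"], n_occasions=10)
            fit = fit_ml(h, designs, OccuModelSpec(["x"], ["w"]))
            est = fit.params.pack()
            se = fit.se
            truth = np.concatenate([beta_true, alpha_true])
            hits += (np.abs(est - truth) <= 1.959963984540054 * se)
        assert (hits >= 40).all(), hits
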