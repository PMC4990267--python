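import itertools

import numpy as np
import pandas as pd
import pytest

from fleetrum.choice import (
    CoefficientSet,
    ConditionalLogit,
    MixedLogit,
    build_design,
    choice_probabilities,
    fit_conditional_logit,
    fit_stratified,
    log_likelihood,
    size_class,
    utility,
)

from conftest import sample_occasions


class TestDesignMatrix:
    def test_z_block_layout_r3(self):
        occs, _ = sample_occasions(np.random.default_rng(0), 1, R=3, K=0, J=1)
        occ = occs[0].__class__(**{**occs[0].__dict__, "Z": np.array([2.0])})
        d = build_design(occ, base_alt=3)
        assert d.shape == (3, 2)
        assert np.array_equal(d, np.array([[2.0, 0.0], [0.0, 2.0], [0.0, 0.0]]))

    def test_base_alt_row_is_zero(self):
        rng = np.random.default_rng(1)
        occs, _ = sample_occasions(rng, 10, R=5, K=2, J=3)
        for occ in occs:
            d = build_design(occ, base_alt=5)
            assert np.all(d[4, 2:] == 0.0)
            # within each Z feature's block, region columns are orthogonal
            for j in range(3):
                zb = d[:, 2 + 4 * j : 2 + 4 * (j + 1)]
                gram = zb.T @ zb
                assert np.count_nonzero(gram - np.diag(np.diag(gram))) == 0

    def test_dimension_arithmetic(self):
        occs, _ = sample_occasions(np.random.default_rng(2), 1, R=12, K=4, J=6)
        assert build_design(occs[0], base_alt=12).shape == (12, 4 + 66)

    def test_non_finite_covariates_rejected(self):
        occs, _ = sample_occasions(np.random.default_rng(3), 1, R=3, K=1, J=1)
        occ = occs[0]
        bad = occ.__class__(**{**occ.__dict__, "X": occ.X * np.nan})
        with pytest.raises(ValueError, match="non-finite"):
            build_design(bad, base_alt=3)


class TestUtilityAndProbabilities:
    def test_zero_coefficients_zero_utility(self):
        occs, truth = sample_occasions(np.random.default_rng(4), 1, R=4, K=2, J=2)
        d = build_design(occs[0], base_alt=4)
        assert np.allclose(utility(d, truth), 0.0)

    def test_hand_multiplication(self):
        occs, _ = sample_occasions(np.random.default_rng(5), 1, R=3, K=1, J=0)
        occ = occs[0].__class__(
            **{**occs[0].__dict__, "X": np.array([[1.0], [2.0], [3.0]])}
        )
        c = CoefficientSet(
            beta=[0.5], theta=np.zeros((0, 3)), base_alt=3, x_names=("x0",)
        )
        d = build_design(occ, base_alt=3)
        assert np.allclose(utility(d, c), [0.5, 1.0, 1.5])

    def test_base_alt_gets_no_theta_contribution(self):
        rng = np.random.default_rng(6)
        theta = rng.normal(size=(2, 4))
        theta[:, 3] = 0.0
        c = CoefficientSet(beta=np.zeros(0), theta=theta, base_alt=4)
        occs, _ = sample_occasions(rng, 5, R=4, K=0, J=2)
        for occ in occs:
            V = utility(build_design(occ, base_alt=4), c)
            assert V[3] == 0.0

    def test_uniform_and_closed_form(self):
        assert np.allclose(choice_probabilities(np.zeros(3)), 1 / 3)
        assert np.allclose(
            choice_probabilities(np.array([np.log(2.0), 0.0])), [2 / 3, 1 / 3]
        )

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            V = rng.normal(scale=5, size=8)
            p1 = choice_probabilities(V)
            p2 = choice_probabilities(V + rng.normal() * 100)
            assert np.allclose(p1, p2, atol=1e-12)
            assert abs(p1.sum() - 1.0) < 1e-12
            assert np.argmax(p1) == np.argmax(V)

    def test_overflow_safety_and_errors(self):
        p = choice_probabilities(np.array([1000.0, 0.0]))
        assert p[0] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            choice_probabilities(np.array([np.inf, 0.0]))

    def test_nonzero_theta_base_column_rejected(self):
        with pytest.raises(ValueError, match="base"):
            CoefficientSet(beta=np.zeros(1), theta=np.ones((1, 3)), base_alt=3)


class TestLogLikelihood:
    def test_zero_params_equal_shares(self):
        occs, truth = sample_occasions(np.random.default_rng(8), 40, R=5, K=2, J=1)
        lnl, _ = log_likelihood(truth, occs)
        assert lnl == pytest.approx(40 * np.log(1 / 5), abs=1e-10)

    def test_matches_per_occasion_loop_oracle(self):
        rng = np.random.default_rng(9)
        theta = rng.normal(size=(2, 4))
        theta[:, 3] = 0.0
        occs, _ = sample_occasions(rng, 5, R=4, K=3, J=2)
        c = CoefficientSet(
            beta=rng.normal(size=3), theta=theta, base_alt=4,
            x_names=occs[0].x_names, z_names=occs[0].z_names,
        )
        lnl, _ = log_likelihood(c, occs)
        oracle = 0.0
        for occ in occs:
            V = utility(build_design(occ, base_alt=4), c)
            oracle += np.log(choice_probabilities(V)[occ.chosen - 1])
        assert lnl == pytest.approx(oracle, rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(10)
        occs, _ = sample_occasions(rng, 5, R=4, K=2, J=2)
        model = ConditionalLogit(occs)
        params = rng.normal(scale=0.5, size=model.nparams)
        g = model.score(params)
        eps = 1e-6
        for i in range(model.nparams):
            e = np.zeros_like(params)
            e[i] = eps
            fd = (model.loglike(params + e) - model.loglike(params - e)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_hessian_matches_finite_difference_of_score(self):
        rng = np.random.default_rng(11)
        occs, _ = sample_occasions(rng, 6, R=3, K=2, J=2)
        model = ConditionalLogit(occs)
        params = rng.normal(scale=0.3, size=model.nparams)
        H = model.hessian(params)
        assert np.allclose(H, H.T, atol=1e-10)
        eps = 1e-6
        for i in range(model.nparams):
            e = np.zeros_like(params)
            e[i] = eps
            fd = (model.score(params + e) - model.score(params - e)) / (2 * eps)
            assert np.allclose(H[:, i], fd, rtol=1e-5, atol=1e-7)


class TestFitting:
    def test_grid_search_oracle_small_fixture(self):
        # R=3, K=1, N=20: the MLE must match an exhaustive 1-d grid search
        rng = np.random.default_rng(12)
        occs, _ = sample_occasions(rng, 20, R=3, K=1, J=0, beta=[0.8])
        res = fit_conditional_logit(occs)
        model = ConditionalLogit(occs)
        grid = np.arange(-4.0, 4.0, 1e-3)
        lls = [model.loglike(np.array([b])) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert res.params[0] == pytest.approx(best, abs=1e-3)
        assert res.llf >= max(lls) - 1e-9

    def test_null_truth_estimates_within_3se(self):
        rng = np.random.default_rng(13)
        occs, _ = sample_occasions(rng, 1000, R=4, K=2, J=1)
        res = fit_conditional_logit(occs)
        assert res.converged
        assert np.all(np.abs(res.params) <= 3.0 * res.bse)

    def test_parameter_recovery_direct_sampling(self):
        rng = np.random.default_rng(14)
        theta = np.array([[0.5, -0.4, 0.2, 0.0], [-0.3, 0.1, 0.6, 0.0]])
        occs, truth = sample_occasions(
            rng, 5000, R=4, K=2, J=2, beta=[0.7, -1.1], theta=theta
        )
        res = fit_conditional_logit(occs)
        assert res.converged and not res.separation
        assert np.all(np.abs(res.params - truth.pack()) <= 3.0 * res.bse)

    def test_global_concavity_multistart(self):
        rng = np.random.default_rng(15)
        occs, _ = sample_occasions(rng, 200, R=3, K=2, J=1, beta=[0.5, -0.5])
        fits = [
            fit_conditional_logit(occs, init=rng.normal(scale=2.0, size=4))
            for _ in range(5)
        ]
        lls = [f.llf for f in fits]
        assert max(lls) - min(lls) < 1e-6
        for f in fits[1:]:
            assert np.allclose(f.params, fits[0].params, atol=1e-4)

    def test_probabilities_invariant_to_x_level_shift(self):
        rng = np.random.default_rng(16)
        occs, _ = sample_occasions(rng, 50, R=4, K=2, J=1, beta=[0.6, -0.2])
        res = fit_conditional_logit(occs)
        shifted = [
            o.__class__(**{**o.__dict__, "X": o.X + 7.5}) for o in occs
        ]
        p1 = res.predict()
        p2 = res.predict(shifted)
        assert np.allclose(p1, p2, atol=1e-10)

    def test_llf_never_below_null(self):
        rng = np.random.default_rng(17)
        occs, _ = sample_occasions(rng, 100, R=3, K=1, J=1, beta=[1.0])
        res = fit_conditional_logit(occs)
        assert res.llf >= res.llnull

    def test_separation_is_flagged(self):
        # deterministic choices: chosen = argmax of a single X feature
        rng = np.random.default_rng(18)
        occs, _ = sample_occasions(rng, 60, R=3, K=1, J=0)
        sep = [
            o.__class__(**{**o.__dict__, "chosen": int(np.argmax(o.X[:, 0])) + 1})
            for o in occs
        ]
        with pytest.warns(UserWarning, match="separation"):
            res = fit_conditional_logit(sep)
        assert res.separation

    def test_rmse_shrinks_with_sample_size(self):
        # root-N consistency: RMSE over replicates ~ halves as N x4
        beta = [0.8]
        rmses = {}
        for N in (250, 1000):
            errs = []
            for rep in range(12):
                rng = np.random.default_rng(1000 + 31 * rep + N)
                occs, _ = sample_occasions(rng, N, R=3, K=1, J=0, beta=beta)
                res = fit_conditional_logit(occs)
                errs.append(res.params[0] - beta[0])
            rmses[N] = float(np.sqrt(np.mean(np.square(errs))))
        ratio = rmses[250] / rmses[1000]
        assert 1.25 <= ratio <= 3.2  # ~2 expected for a 4x sample increase


class TestSizeClassAndStrata:
    @pytest.mark.parametrize(
        "capacity,expected",
        [(363, "small"), (699.9, "small"), (700, "medium"), (1049.9, "medium"),
         (1050, "large"), (1250, "xlarge"), (1800, "xlarge")],
    )
    def test_half_open_boundaries(self, capacity, expected):
        assert size_class(capacity) == expected

    @pytest.mark.parametrize("capacity", [100.0, 1800.1])
    def test_out_of_range_rejected(self, capacity):
        with pytest.raises(ValueError):
            size_class(capacity)

    def test_single_stratum_fleet_yields_two_models(self):
        rng = np.random.default_rng(19)
        first, _ = sample_occasions(rng, 60, R=3, K=1, J=0, beta=[0.5])
        switch, _ = sample_occasions(rng, 60, R=3, K=1, J=0, beta=[0.5])
        first = [o.__class__(**{**o.__dict__, "stage": "first"}) for o in first]
        registry = pd.DataFrame(
            [{"vessel_id": "V", "capacity_t": 500.0, "dml": 0}]
        )
        fits = fit_stratified(first + switch, registry, min_occasions=10)
        assert fits.n_models == 2
        assert len(fits.skipped) == 14
        assert set(k[2] for k in fits.results) == {"first", "switch"}

    def test_unregistered_vessel_rejected(self):
        rng = np.random.default_rng(20)
        occs, _ = sample_occasions(rng, 10, R=3, K=1, J=0)
        registry = pd.DataFrame(
            [{"vessel_id": "OTHER", "capacity_t": 500.0, "dml": 0}]
        )
        with pytest.raises(KeyError):
            fit_stratified(occs, registry)

    def test_coefficient_table_layout(self):
        rng = np.random.default_rng(21)
        occs, _ = sample_occasions(rng, 80, R=3, K=2, J=1)
        res = fit_conditional_logit(occs)
        df = res.to_frame()
        assert list(df.columns) == [
            "stratum", "stage", "feature", "region_or_shared", "estimate", "se", "z",
        ]
        assert len(df) == 2 + 1 * 2  # K shared rows + J*(R-1) region rows
        assert res.summary()  # renders


class TestMixedLogitMode:
    def test_collapses_to_conditional_when_sd_zero(self):
        rng = np.random.default_rng(22)
        occs, _ = sample_occasions(rng, 50, R=3, K=1, J=0, beta=[0.6])
        cl = ConditionalLogit(occs)
        ml = MixedLogit(occs, random_features=["x0"], n_draws=32, seed=1)
        params = np.array([0.6])
        assert ml.simulated_loglike(np.array([0.6, 0.0])) == pytest.approx(
            cl.loglike(params), rel=1e-10
        )

    def test_fit_runs_on_small_problem(self):
        rng = np.random.default_rng(23)
        occs, _ = sample_occasions(rng, 80, R=3, K=1, J=0, beta=[0.5])
        ml = MixedLogit(occs, random_features=["x0"], n_draws=16, seed=2)
        res = ml.fit_mixed(maxiter=50)
        assert np.isfinite(res.fun)
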