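"""Model definition: likelihood, log full conditionals, gradients, and the
conjugate Inverse-Gamma update, all cross-checked against independent
oracles (the full joint log posterior, finite differences, and grid
normalization)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from centerprofile.model import (
    CohortData,
    Hyperparameters,
    ParameterState,
    bernoulli_loglik,
    grad_alpha,
    grad_beta,
    grad_u,
    ig_full_conditional_params,
    linear_predictor,
    log_conditional_alpha,
    log_conditional_beta,
    log_conditional_u,
    log_joint_posterior,
    logistic,
)

from conftest import random_cohort, random_state


def empty_cohort():
    return CohortData(
        y=np.empty(0), X=np.empty((0, 0)), center_index=np.empty(0, dtype=int),
        center_labels=(),
    )


class TestLogistic:
    def test_point_values(self):
        assert logistic(0.0) == 0.5
        assert abs(logistic(40.0) - 1.0) < 1e-15
        assert logistic(-2.38) == pytest.approx(0.0847, abs=5e-5)

    def test_overflow_safe(self):
        out = logistic(np.array([-700.0, 700.0]))
        assert np.isfinite(out).all()
        assert 0.0 <= out[0] < out[1] <= 1.0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            logistic(np.inf)
        with pytest.raises(ValueError):
            logistic(np.array([0.0, np.nan]))

    @given(st.floats(-500, 500), st.floats(-500, 500))
    @settings(derandomize=True, max_examples=50)
    def test_bounded_and_monotone(self, a, b):
        pa, pb = logistic(a), logistic(b)
        assert 0.0 <= pa <= 1.0
        if a < b:
            assert pa <= pb


class TestLinearPredictor:
    def test_zero_state(self, small_cohort):
        state = ParameterState(0.0, np.zeros(3), np.zeros(4), 1.0)
        assert np.all(linear_predictor(state, small_cohort) == 0.0)

    def test_arithmetic(self):
        data = CohortData(
            y=[1], X=[[1.0]], center_index=[0], center_labels=("A",)
        )
        state = ParameterState(1.0, np.array([2.0]), np.array([-0.5]), 1.0)
        assert linear_predictor(state, data)[0] == pytest.approx(2.5)

    def test_matches_per_patient_loop(self, rng, small_cohort):
        state = random_state(rng)
        eta = linear_predictor(state, small_cohort)
        for i in range(small_cohort.n_patients):
            want = (
                state.alpha
                + small_cohort.X[i] @ state.beta
                + state.u[small_cohort.center_index[i]]
            )
            assert eta[i] == pytest.approx(want, abs=1e-12)

    def test_dimension_mismatch(self, small_cohort):
        state = ParameterState(0.0, np.zeros(2), np.zeros(4), 1.0)
        with pytest.raises(ValueError):
            linear_predictor(state, small_cohort)


class TestBernoulliLoglik:
    def test_fair_coin_values(self):
        assert bernoulli_loglik([1], [0.0]) == pytest.approx(np.log(0.5))
        assert bernoulli_loglik([0, 1], [0.0, 0.0]) == pytest.approx(
            2 * np.log(0.5)
        )

    def test_matches_product_form_oracle(self, rng):
        y = rng.integers(0, 2, 50)
        eta = rng.normal(0, 2, 50)
        p = 1.0 / (1.0 + np.exp(-eta))
        oracle = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        assert bernoulli_loglik(y, eta) == pytest.approx(oracle, abs=1e-10)

    def test_extreme_eta_finite(self):
        assert np.isfinite(bernoulli_loglik([0, 1], [700.0, -700.0]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bernoulli_loglik([0, 1], [0.0])


class TestConditionalJointConsistency:
    """Differences of each block's log conditional must equal differences
    of the full log joint posterior with the other blocks held fixed."""

    @pytest.mark.parametrize("trial", range(5))
    def test_alpha_block(self, trial):
        rng = np.random.default_rng(100 + trial)
        data = random_cohort(rng, n=rng.integers(10, 100), J=3, p=2)
        hyper = Hyperparameters()
        state = random_state(rng, p=2, J=3)
        a1, a2 = rng.normal(0, 2, 2)
        dc = log_conditional_alpha(a1, state, data, hyper) - log_conditional_alpha(
            a2, state, data, hyper
        )
        dj = log_joint_posterior(state.with_(alpha=a1), data, hyper) - (
            log_joint_posterior(state.with_(alpha=a2), data, hyper)
        )
        assert dc == pytest.approx(dj, abs=1e-10)

    @pytest.mark.parametrize("trial", range(5))
    def test_beta_block(self, trial):
        rng = np.random.default_rng(200 + trial)
        data = random_cohort(rng, n=rng.integers(10, 100), J=5, p=3)
        hyper = Hyperparameters()
        state = random_state(rng, p=3, J=5)
        b1, b2 = rng.normal(0, 1, 3), rng.normal(0, 1, 3)
        dc = log_conditional_beta(b1, state, data, hyper) - log_conditional_beta(
            b2, state, data, hyper
        )
        dj = log_joint_posterior(state.with_(beta=b1), data, hyper) - (
            log_joint_posterior(state.with_(beta=b2), data, hyper)
        )
        assert dc == pytest.approx(dj, abs=1e-10)

    @pytest.mark.parametrize("trial", range(5))
    def test_u_block(self, trial):
        rng = np.random.default_rng(300 + trial)
        data = random_cohort(rng, n=rng.integers(10, 100), J=4, p=2)
        hyper = Hyperparameters()
        state = random_state(rng, p=2, J=4)
        j = int(rng.integers(0, 4))
        v1, v2 = rng.normal(0, 1, 2)
        u1, u2 = state.u.copy(), state.u.copy()
        u1[j], u2[j] = v1, v2
        dc = log_conditional_u(j, v1, state, data, hyper) - log_conditional_u(
            j, v2, state, data, hyper
        )
        dj = log_joint_posterior(state.with_(u=u1), data, hyper) - (
            log_joint_posterior(state.with_(u=u2), data, hyper)
        )
        assert dc == pytest.approx(dj, abs=1e-10)

    def test_sigma2_block_matches_ig_density(self, rng):
        """Joint-posterior differences in sigma2_u alone equal IG(shape,
        rate) log-density differences (the conjugacy consistency check)."""
        data = random_cohort(rng, n=60, J=4, p=2)
        hyper = Hyperparameters()
        state = random_state(rng, p=2, J=4)
        shape, rate = ig_full_conditional_params(state.u, hyper.a0, hyper.b0)
        for _ in range(5):
            s1, s2 = rng.uniform(0.1, 3.0, 2)
            dj = log_joint_posterior(state.with_(sigma2_u=s1), data, hyper) - (
                log_joint_posterior(state.with_(sigma2_u=s2), data, hyper)
            )
            dig = stats.invgamma.logpdf(s1, shape, scale=rate) - (
                stats.invgamma.logpdf(s2, shape, scale=rate)
            )
            assert dj == pytest.approx(dig, abs=1e-10)

    def test_u_conditional_only_uses_center_patients(self, rng):
        """Changing outcomes outside center j leaves the u_j conditional
        difference unchanged."""
        data = random_cohort(rng, n=60, J=3, p=2)
        hyper = Hyperparameters()
        state = random_state(rng, p=2, J=3)
        d0 = log_conditional_u(0, 0.7, state, data, hyper) - log_conditional_u(
            0, -0.4, state, data, hyper
        )
        y2 = data.y.copy()
        mask = data.center_index != 0
        y2[mask] = 1 - y2[mask]
        data2 = CohortData(
            y=y2, X=data.X, center_index=data.center_index,
            center_labels=data.center_labels,
        )
        d1 = log_conditional_u(0, 0.7, state, data2, hyper) - log_conditional_u(
            0, -0.4, state, data2, hyper
        )
        assert d0 == pytest.approx(d1, abs=1e-10)


class TestGradients:
    def _fd(self, f, x, h=1e-5):
        return (f(x + h) - f(x - h)) / (2 * h)

    @pytest.mark.parametrize("trial", range(3))
    def test_grad_alpha_finite_difference(self, trial):
        rng = np.random.default_rng(400 + trial)
        data = random_cohort(rng, n=50, J=3, p=2)
        hyper = Hyperparameters()
        state = random_state(rng, p=2, J=3)
        g = grad_alpha(state, data, hyper)
        fd = self._fd(
            lambda a: log_conditional_alpha(a, state, data, hyper), state.alpha
        )
        assert g == pytest.approx(fd, rel=1e-5)

    @pytest.mark.parametrize("trial", range(3))
    def test_grad_beta_finite_difference(self, trial):
        rng = np.random.default_rng(500 + trial)
        data = random_cohort(rng, n=50, J=3, p=3)
        hyper = Hyperparameters()
        state = random_state(rng, p=3, J=3)
        g = grad_beta(state, data, hyper)
        for k in range(3):
            def f(bk, k=k):
                b = state.beta.copy()
                b[k] = bk
                return log_conditional_beta(b, state, data, hyper)

            assert g[k] == pytest.approx(self._fd(f, state.beta[k]), rel=1e-5)

    @pytest.mark.parametrize("trial", range(3))
    def test_grad_u_finite_difference(self, trial):
        rng = np.random.default_rng(600 + trial)
        data = random_cohort(rng, n=50, J=4, p=2)
        hyper = Hyperparameters()
        state = random_state(rng, p=2, J=4)
        for j in range(4):
            g = grad_u(j, state, data, hyper)
            fd = self._fd(
                lambda v: log_conditional_u(j, v, state, data, hyper), state.u[j]
            )
            assert g == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_grad_alpha_closed_form_point(self):
        """All y = 1 at eta = 0 with alpha = 0 and a flat prior gives
        sum(y - 1/2) = n/2."""
        n = 12
        data = CohortData(
            y=np.ones(n), X=np.empty((n, 0)),
            center_index=np.zeros(n, dtype=int), center_labels=("A",),
        )
        state = ParameterState(0.0, np.empty(0), np.zeros(1), 1.0)
        hyper = Hyperparameters(sigma2_alpha=1e12)
        assert grad_alpha(state, data, hyper) == pytest.approx(n * 0.5)

    def test_grad_zero_at_grid_mode(self):
        """On a tiny intercept-only model the gradient vanishes at the
        mode located by grid search."""
        rng = np.random.default_rng(7)
        n = 30
        y = (rng.uniform(size=n) < 0.3).astype(float)
        data = CohortData(
            y=y, X=np.empty((n, 0)), center_index=np.zeros(n, dtype=int),
            center_labels=("A",),
        )
        hyper = Hyperparameters(sigma2_alpha=4.0)
        state = ParameterState(0.0, np.empty(0), np.zeros(1), 1.0)
        grid = np.linspace(-3, 3, 20001)
        vals = [log_conditional_alpha(a, state, data, hyper) for a in grid]
        mode = grid[int(np.argmax(vals))]
        g = grad_alpha(state.with_(alpha=mode), data, hyper)
        assert abs(g) < 1e-2  # grid spacing limits the attainable precision

    def test_grad_u_prior_vanishes_at_large_sigma(self, rng):
        data = random_cohort(rng, n=40, J=3, p=2)
        hyper = Hyperparameters()
        state = random_state(rng, p=2, J=3).with_(sigma2_u=1e12)
        g = grad_u(0, state, data, hyper)
        eta = linear_predictor(state, data)
        mask = data.center_index == 0
        lik = float(np.sum(data.y[mask] - 1 / (1 + np.exp(-eta[mask]))))
        assert g == pytest.approx(lik, abs=1e-9)


class TestPriorOnlyConditionals:
    def test_alpha_flat_when_prior_vague_and_no_data(self):
        data = empty_cohort()
        state = ParameterState(0.0, np.empty(0), np.empty(0), 1.0)
        hyper = Hyperparameters(sigma2_alpha=1e12)
        d = log_conditional_alpha(3.0, state, data, hyper) - (
            log_conditional_alpha(-3.0, state, data, hyper)
        )
        assert abs(d) < 1e-8

    def test_alpha_quadratic_when_no_data(self):
        data = empty_cohort()
        state = ParameterState(0.0, np.empty(0), np.empty(0), 1.0)
        hyper = Hyperparameters(sigma2_alpha=1.0)
        for a in (-2.0, 0.5, 1.7):
            assert log_conditional_alpha(a, state, data, hyper) == pytest.approx(
                -a * a / 2.0
            )


class TestInverseGammaConditional:
    def test_arithmetic_examples(self):
        assert ig_full_conditional_params(np.zeros(34), 1.0, 1.0) == (18.0, 1.0)
        assert ig_full_conditional_params(np.array([1.0, 1.0]), 1.0, 1.0) == (
            2.0,
            2.0,
        )

    def test_empty_u_rejected(self):
        with pytest.raises(ValueError):
            ig_full_conditional_params(np.empty(0), 1.0, 1.0)

    def test_matches_grid_normalization(self, rng):
        """The IG(shape, rate) density equals the normalized product of
        the N(0, sigma2) likelihood of the random effects and the
        IG(a0, b0) prior, evaluated on a sigma2 grid (sup-norm 1e-6)."""
        u = rng.normal(0, 0.8, 3)
        a0, b0 = 1.0, 1.0
        grid = np.linspace(1e-3, 12.0, 60001)
        log_lik = -0.5 * len(u) * np.log(grid) - np.sum(u**2) / (2 * grid)
        log_prior = -(a0 + 1) * np.log(grid) - b0 / grid
        dens = np.exp(log_lik + log_prior - (log_lik + log_prior).max())
        dens /= np.trapezoid(dens, grid)
        shape, rate = ig_full_conditional_params(u, a0, b0)
        ig = stats.invgamma.pdf(grid, shape, scale=rate)
        ig /= np.trapezoid(ig, grid)
        assert np.max(np.abs(dens - ig)) < 1e-6


class TestLogJointPosterior:
    def test_rejects_nonpositive_variance(self, rng, small_cohort, hyper):
        state = random_state(rng)
        with pytest.raises(ValueError):
            log_joint_posterior(state.with_(sigma2_u=-1.0), small_cohort, hyper)

    def test_finite_for_extreme_states(self, rng, small_cohort, hyper):
        state = random_state(rng)
        for a in (-30.0, 30.0):
            assert np.isfinite(
                log_joint_posterior(state.with_(alpha=a), small_cohort, hyper)
            )


class TestCohortValidation:
    def test_rejects_nonbinary_outcome(self):
        with pytest.raises(ValueError):
            CohortData(
                y=[0, 2], X=[[0.0], [1.0]], center_index=[0, 0],
                center_labels=("A",),
            )

    def test_rejects_empty_center(self):
        with pytest.raises(ValueError):
            CohortData(
                y=[0, 1], X=[[0.0], [1.0]], center_index=[0, 0],
                center_labels=("A", "B"),
            )

    def test_rejects_out_of_range_center(self):
        with pytest.raises(ValueError):
            CohortData(
                y=[0, 1], X=[[0.0], [1.0]], center_index=[0, 3],
                center_labels=("A", "B"),
            )
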