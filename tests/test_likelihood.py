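import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from readrel.corpus import CorpusConfig, simulate_responses
from readrel.model import ModelSpec, build_design
from readrel.model.design import DesignMatrixBundle
from readrel.model.likelihood import (
    bivariate_normal_loglik,
    family_loglik,
    linear_predictor,
    lkj2_logpdf,
    log_density,
)
from readrel.model.marginal import MarginalModel, block_covariances
from conftest import single_predictor_specs


def one_row_bundle(x1=2.0, delta_v=1.0, y=250.0, x_lag=None):
    return DesignMatrixBundle(
        subject_ids=np.array([0]),
        subject_idx=np.array([0]),
        delta_v=np.array([delta_v]),
        X=np.array([[x1]]),
        X_lag=None if x_lag is None else np.array([[x_lag]]),
        y=np.array([y]),
        predictors=("wl",),
        session_labels=("u", "v"),
        n_rows_u=int(delta_v == 0),
        n_rows_v=int(delta_v == 1),
    )


def zero_params(n_blocks=2, **overrides):
    params = {
        "beta0": 0.0,
        "beta_v": 0.0,
        "beta": np.zeros(1),
        "b": np.zeros((n_blocks, 1, 2)),
        "sd": np.full((n_blocks, 2), 0.1),
        "rho": np.zeros(n_blocks),
        "sigma": 0.5,
    }
    params.update(overrides)
    return params


class TestLinearPredictor:
    def test_all_zero(self):
        theta = linear_predictor(zero_params(), one_row_bundle())
        assert theta == pytest.approx([0.0])

    def test_hand_arithmetic_session_v(self):
        params = zero_params(
            beta0=5.5, beta_v=-0.1, beta=np.array([0.05])
        )
        theta = linear_predictor(params, one_row_bundle(x1=2.0, delta_v=1.0))
        assert theta == pytest.approx([5.5 - 0.1 + 0.1])

    def test_hand_arithmetic_spillover_row(self):
        b = np.zeros((3, 1, 2))
        b[2, 0, 0] = 0.02  # lagged-slope block, session u
        params = zero_params(n_blocks=3, b=b)
        bundle = one_row_bundle(x1=0.0, delta_v=0.0, x_lag=1.5)
        theta = linear_predictor(params, bundle)
        assert theta == pytest.approx([0.03])

    def test_random_effects_enter_by_session(self):
        b = np.zeros((2, 1, 2))
        b[0, 0, 0] = 0.3  # intercept, session u
        b[1, 0, 1] = 0.1  # slope, session v
        params = zero_params(b=b)
        theta_u = linear_predictor(params, one_row_bundle(x1=2.0, delta_v=0.0))
        theta_v = linear_predictor(params, one_row_bundle(x1=2.0, delta_v=1.0))
        assert theta_u == pytest.approx([0.3])
        assert theta_v == pytest.approx([0.2])


class TestLogDensity:
    def test_single_lognormal_observation_hand_composed(self):
        spec = ModelSpec(family="lognormal", predictors=("wl",))
        bundle = one_row_bundle(x1=1.0, delta_v=0.0, y=250.0)
        params = zero_params(beta0=5.5, sigma=0.4)
        got = log_density(params, bundle, spec)

        theta = 5.5
        expected = stats.norm.logpdf(np.log(250.0), theta, 0.4) - np.log(250.0)
        pr = spec.priors
        expected += stats.norm.logpdf(5.5, pr.beta0.loc, pr.beta0.scale)
        expected += 2 * stats.norm.logpdf(0.0, pr.beta.loc, pr.beta.scale)
        expected += (np.log(pr.sd_rate) - pr.sd_rate * 0.1) * 4
        expected += 2 * lkj2_logpdf(0.0, pr.lkj_eta)
        expected += np.log(pr.sigma_rate) - pr.sigma_rate * 0.4
        # two blocks of one subject's (0,0) random effects
        expected += 2 * bivariate_normal_loglik(
            np.zeros((1, 2)), np.array([0.1, 0.1]), 0.0
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_bernoulli_at_zero_theta_is_log_half(self):
        ll = family_loglik(np.array([0.0, 1.0]), np.zeros(2), "bernoulli")
        assert ll == pytest.approx([np.log(0.5)] * 2)

    def test_zip_reduces_to_poisson_when_pi_zero(self):
        y = np.array([0.0, 1.0, 3.0, 7.0])
        theta = np.array([0.2, 0.5, 1.0, 1.5])
        got = family_loglik(y, theta, "zip", zip_logit_pi=-40.0)
        want = stats.poisson.logpmf(y, np.exp(theta))
        assert got == pytest.approx(want, abs=1e-10)

    def test_out_of_support_returns_minus_inf(self):
        spec = ModelSpec(family="lognormal", predictors=("wl",))
        bundle = one_row_bundle()
        assert log_density(zero_params(sigma=-1.0), bundle, spec) == -np.inf
        assert (
            log_density(zero_params(rho=np.array([0.0, 1.5])), bundle, spec)
            == -np.inf
        )

    def test_truth_beats_distant_parameters_on_simulated_data(self):
        cfg = CorpusConfig(
            n_subjects=8,
            words_per_session=(60, 60),
            effect_specs=single_predictor_specs(),
            seed=21,
        )
        trials, truth = simulate_responses(cfg)
        spec = ModelSpec(family="lognormal", predictors=("wl",))
        bundle = build_design(trials, spec)
        b_true = np.stack(
            [
                np.asarray(truth["random_effects"]["intercept"]),
                np.asarray(truth["random_effects"]["wl"]),
            ]
        )
        params = {
            "beta0": truth["beta0"],
            "beta_v": truth["session_effect"],
            "beta": np.array([truth["effects"]["wl"]["beta"]]),
            "b": b_true,
            "sd": np.array([[0.2, 0.2], [0.05, 0.05]]),
            "rho": np.array([0.7, 0.75]),
            "sigma": truth["sigma"],
        }
        at_truth = log_density(params, bundle, spec)
        assert np.isfinite(at_truth)
        far = dict(params, beta0=truth["beta0"] + 5.0, sigma=truth["sigma"] * 8)
        assert at_truth > log_density(far, bundle, spec)


class TestMarginalization:
    def _mc_marginal(self, bundle, beta, cov, family, sigma=None, ndraw=200_000):
        rng = np.random.default_rng(42)
        total = 0.0
        for i in range(bundle.n_subjects):
            mask = bundle.subject_idx == i
            theta_base = (
                beta[0]
                + beta[1] * bundle.delta_v[mask]
                + beta[2] * bundle.X[mask, 0]
            )
            s = bundle.delta_v[mask].astype(int)
            b0 = rng.multivariate_normal(np.zeros(2), cov[0], size=ndraw)
            b1 = rng.multivariate_normal(np.zeros(2), cov[1], size=ndraw)
            theta = (
                theta_base[None, :]
                + b0[:, s]
                + b1[:, s] * bundle.X[mask, 0][None, :]
            )
            if family == "lognormal":
                ly = np.log(bundle.y[mask])
                ll = (
                    stats.norm.logpdf(ly[None, :], theta, sigma)
                    - ly[None, :]
                ).sum(axis=1)
            else:
                y = bundle.y[mask]
                ll = (y[None, :] * theta - np.logaddexp(0, theta)).sum(axis=1)
            total += logsumexp(ll) - np.log(ndraw)
        return total

    def test_exact_lognormal_marginal_matches_monte_carlo(self):
        cfg = CorpusConfig(
            n_subjects=3,
            words_per_session=(5, 5),
            effect_specs=single_predictor_specs(),
            seed=42,
        )
        trials, _ = simulate_responses(cfg)
        spec = ModelSpec(family="lognormal", predictors=("wl",))
        bundle = build_design(trials, spec)
        model = MarginalModel(bundle, spec)
        beta = np.array([5.4, -0.02, 0.06])
        cov = block_covariances(
            np.array([[0.2, 0.2], [0.05, 0.05]]), np.array([0.7, 0.75])
        )
        exact = model.loglik_lognormal(beta, 0.45, cov)
        mc = self._mc_marginal(bundle, beta, cov, "lognormal", sigma=0.45)
        assert exact == pytest.approx(mc, abs=0.05)

    def test_laplace_marginal_matches_monte_carlo_for_bernoulli(self):
        cfg = CorpusConfig(
            n_subjects=3,
            words_per_session=(6, 6),
            family="bernoulli",
            sigma=None,
            beta0=-1.0,
            session_effect=0.1,
            effect_specs=single_predictor_specs(),
            seed=7,
        )
        trials, _ = simulate_responses(cfg)
        spec = ModelSpec(family="bernoulli", predictors=("wl",))
        bundle = build_design(trials, spec)
        model = MarginalModel(bundle, spec)
        beta = np.array([-1.0, 0.1, 0.05])
        cov = block_covariances(
            np.array([[0.2, 0.2], [0.05, 0.05]]), np.array([0.7, 0.75])
        )
        lap = model.loglik_laplace(beta, cov, {})
        mc = self._mc_marginal(bundle, beta, cov, "bernoulli")
        assert lap == pytest.approx(mc, abs=0.05)

    def test_collapsed_fixed_effects_match_direct_integration(self):
        """Integrating beta analytically equals quadrature over a beta grid."""
        cfg = CorpusConfig(
            n_subjects=3,
            words_per_session=(4, 4),
            effect_specs=single_predictor_specs(),
            seed=13,
        )
        trials, _ = simulate_responses(cfg)
        spec = ModelSpec(family="lognormal", predictors=("wl",))
        bundle = build_design(trials, spec)
        model = MarginalModel(bundle, spec)
        cov = block_covariances(
            np.array([[0.2, 0.2], [0.05, 0.05]]), np.array([0.7, 0.75])
        )
        # a prior tight enough that plain Monte Carlo over it is accurate
        prior_mean = np.array([5.5, 0.0, 0.0])
        prior_var = np.array([0.04, 0.01, 0.01])
        closed = model.loglik_lognormal_intbeta(
            0.45, cov, prior_mean, prior_var
        )
        rng = np.random.default_rng(5)
        betas = prior_mean + np.sqrt(prior_var) * rng.standard_normal(
            (20000, 3)
        )
        lls = np.array(
            [model.loglik_lognormal(b, 0.45, cov) for b in betas]
        )
        mc = logsumexp(lls) - np.log(len(betas))
        assert closed == pytest.approx(mc, abs=0.05)
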