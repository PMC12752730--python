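"""Linear predictor and joint log posterior density of the two-task model.

Parameter layout (the ``params`` dict):

- ``beta0`` (float): global intercept.
- ``beta_v`` (float): session/method effect, treatment-coded (added on
  session-v rows only).
- ``beta`` (M,): population-level slopes of the z-scored predictors.
- ``beta_spill`` (M,), optional: population-level spillover slopes (off by
  default; the spillover terms enter as random slopes only).
- ``b`` (B, S, 2): per-block, per-subject random effects for sessions
  (u, v).  Block 0 is the random intercept, blocks 1..M the predictor
  slopes, blocks M+1..2M the lagged-predictor slopes when spillover is on.
- ``sd`` (B, 2) and ``rho`` (B,): bivariate-normal parameters of each
  random-effect block; ``rho[b]`` is the reliability parameter of block b.
- ``sigma`` (float): residual sd on the log scale (lognormal family only).
- ``zip_logit_pi`` (float): intercept-only zero-inflation on the logit
  scale (zip family only).

The response mean is ``inverse-link(theta)``: identity on the log-scale
location for the lognormal family, inverse-logit for Bernoulli, exp for the
Poisson part of the zero-inflated Poisson.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .design import DesignMatrixBundle
from .spec import ModelSpec, PriorSet

__all__ = [
    "linear_predictor",
    "log_density",
    "family_loglik",
    "lkj2_logpdf",
    "bivariate_normal_loglik",
]


def linear_predictor(params: dict, bundle: DesignMatrixBundle) -> np.ndarray:
    """Evaluate theta for every row of the bundle.

    theta = beta0 + b0[i,s] + beta_v * delta_v
            + sum_m (beta_m + b_m[i,s]) x_m
            + sum_m (beta_spill_m + b_{M+m}[i,s]) x_lag_m      (spillover)
    """
    i = bundle.subject_idx
    s = bundle.delta_v.astype(int)
    b = np.asarray(params["b"], dtype=float)
    beta = np.atleast_1d(np.asarray(params["beta"], dtype=float))
    M = len(bundle.predictors)
    if beta.size != M:
        raise ValueError("beta has wrong length for the bundle predictors")

    theta = params["beta0"] + params["beta_v"] * bundle.delta_v + b[0, i, s]
    for m in range(M):
        theta = theta + (beta[m] + b[1 + m, i, s]) * bundle.X[:, m]
    if bundle.X_lag is not None:
        if b.shape[0] < 1 + 2 * M:
            raise ValueError("missing spillover random-effect blocks")
        beta_spill = params.get("beta_spill")
        for m in range(M):
            slope = b[1 + M + m, i, s]
            if beta_spill is not None:
                slope = slope + beta_spill[m]
            theta = theta + slope * bundle.X_lag[:, m]
    return theta


def family_loglik(y: np.ndarray, theta: np.ndarray, family: str,
                  sigma: float | None = None,
                  zip_logit_pi: float | None = None) -> np.ndarray:
    """Per-observation log likelihood for the given family."""
    if family == "lognormal":
        if sigma is None or sigma <= 0:
            return np.full_like(theta, -np.inf)
        logy = np.log(y)
        return stats.norm.logpdf(logy, theta, sigma) - logy
    if family == "bernoulli":
        return y * theta - np.logaddexp(0.0, theta)
    if family == "zip":
        if zip_logit_pi is None:
            raise ValueError("zip family needs zip_logit_pi")
        log_pi = -np.logaddexp(0.0, -zip_logit_pi)
        log_1mpi = -np.logaddexp(0.0, zip_logit_pi)
        lam = np.exp(theta)
        pois = y * theta - lam - gammaln(y + 1.0)
        zero = np.logaddexp(log_pi, log_1mpi - lam)
        return np.where(y == 0, zero, log_1mpi + pois)
    raise ValueError(f"unknown family {family!r}")


def bivariate_normal_loglik(b: np.ndarray, sd: np.ndarray, rho: float) -> float:
    """Sum of zero-mean bivariate normal log densities over the rows of b."""
    su, sv = sd
    if su <= 0 or sv <= 0 or not -1 < rho < 1:
        return -np.inf
    z_u = b[:, 0] / su
    z_v = b[:, 1] / sv
    one_m_r2 = 1.0 - rho * rho
    quad = (z_u**2 - 2.0 * rho * z_u * z_v + z_v**2) / one_m_r2
    n = b.shape[0]
    return float(
        -0.5 * quad.sum()
        - n * (np.log(2 * np.pi) + np.log(su) + np.log(sv)
               + 0.5 * np.log(one_m_r2))
    )


def lkj2_logpdf(rho: float, eta: float) -> float:
    """Log density of the off-diagonal of a 2x2 LKJ(eta) correlation matrix.

    Equivalent to (rho + 1)/2 ~ Beta(eta, eta), i.e. proportional to
    (1 - rho^2)^(eta - 1) on (-1, 1).
    """
    if not -1 < rho < 1:
        return -np.inf
    return float(stats.beta.logpdf((rho + 1.0) / 2.0, eta, eta) - np.log(2.0))


def _log_priors(params: dict, spec: ModelSpec) -> float:
    pr: PriorSet = spec.priors
    lp = stats.norm.logpdf(params["beta0"], pr.beta0.loc, pr.beta0.scale)
    lp += stats.norm.logpdf(params["beta_v"], pr.beta.loc, pr.beta.scale)
    lp += stats.norm.logpdf(
        np.asarray(params["beta"]), pr.beta.loc, pr.beta.scale
    ).sum()
    if params.get("beta_spill") is not None:
        lp += stats.norm.logpdf(
            np.asarray(params["beta_spill"]), pr.beta.loc, pr.beta.scale
        ).sum()
    sd = np.asarray(params["sd"], dtype=float)
    rho = np.atleast_1d(np.asarray(params["rho"], dtype=float))
    if (sd <= 0).any() or (np.abs(rho) >= 1).any():
        return -np.inf
    lp += (np.log(pr.sd_rate) - pr.sd_rate * sd).sum()
    lp += sum(lkj2_logpdf(r, pr.lkj_eta) for r in rho)
    if spec.family == "lognormal":
        sigma = params["sigma"]
        if sigma <= 0:
            return -np.inf
        lp += np.log(pr.sigma_rate) - pr.sigma_rate * sigma
    if spec.family == "zip":
        lp += stats.norm.logpdf(
            params["zip_logit_pi"], pr.zip_logit.loc, pr.zip_logit.scale
        )
    return float(lp)


def log_density(params: dict, bundle: DesignMatrixBundle,
                spec: ModelSpec) -> float:
    """Joint log posterior (likelihood + random effects + priors).

    Returns ``-inf`` (rather than raising) for parameter values outside the
    support: non-positive sds or sigma, |rho| >= 1.
    """
    lp = _log_priors(params, spec)
    if not np.isfinite(lp):
        return -np.inf
    b = np.asarray(params["b"], dtype=float)
    sd = np.asarray(params["sd"], dtype=float)
    rho = np.atleast_1d(np.asarray(params["rho"], dtype=float))
    if b.shape[0] != spec.n_blocks or sd.shape[0] != spec.n_blocks:
        raise ValueError("random-effect arrays do not match spec.n_blocks")
    for blk in range(spec.n_blocks):
        lp += bivariate_normal_loglik(b[blk], sd[blk], float(rho[blk]))
        if not np.isfinite(lp):
            return -np.inf
    theta = linear_predictor(params, bundle)
    ll = family_loglik(
        bundle.y, theta, spec.family,
        sigma=params.get("sigma"),
        zip_logit_pi=params.get("zip_logit_pi"),
    )
    total = lp + ll.sum()
    return float(total) if np.isfinite(total) else -np.inf
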