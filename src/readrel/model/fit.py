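"""Posterior sampling for the two-task model and the posterior container.

Sampling runs on a marginalized posterior (see :mod:`readrel.model.marginal`).
For the lognormal family both the per-subject random effects *and* the fixed
effects are integrated out analytically — the Gaussian fixed-effect prior is
conjugate given the variance parameters — so the sampler explores only the
random-effect sds, their correlations and the residual sd.  Fixed and random
effects are reattached afterwards by drawing from their exact Gaussian
conditionals, yielding draws from the full joint posterior.  For the
Bernoulli and zero-inflated-Poisson families the random effects are collapsed
by a Laplace approximation and the fixed effects stay in the sampled vector.

The space is explored with ensemble MCMC (emcee, differential-evolution
moves); ``chains`` independent ensembles are run from overdispersed starts
so split-R-hat can be computed across them.  Parameters are sampled on
unconstrained scales (log sds, atanh correlations, log sigma) with Jacobian
corrections, so the posterior over the natural parameters is the one defined
by :func:`readrel.model.likelihood.log_density`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np
from scipy.special import betaln

from .design import DesignMatrixBundle
from .diagnostics import rhat
from .marginal import MarginalModel, block_covariances
from .spec import ModelSpec, SamplerConfig

__all__ = ["fit", "FitError", "TwoTaskPosterior"]

_LOG2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """Sampler failure; carries the diagnostics collected before the abort."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class TwoTaskPosterior:
    """Posterior draws and metadata of a two-task model fit.

    Parameter draws are stored per chain with shape ``(chains, draws, ...)``;
    per-subject random-effect draws (a thinned subset of the joint posterior)
    with shape ``(n_subset, blocks, subjects, 2)``.
    """

    spec: ModelSpec
    block_names: tuple[str, ...]
    draws: dict[str, np.ndarray]
    b_draws: np.ndarray | None
    subject_ids: np.ndarray
    rhat: dict[str, float]
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws["rho"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["rho"].shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All draws of a parameter with the chain axis flattened."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def rho_draws(self, block: str) -> np.ndarray:
        """Flattened reliability-correlation draws for a named block."""
        if block not in self.block_names:
            raise KeyError(f"unknown random-effect block {block!r}")
        return self.flat("rho")[:, self.block_names.index(block)]

    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def converged(self, threshold: float = 1.01) -> bool:
        return self.max_rhat() < threshold


# ---------------------------------------------------------------------------
# parameter-vector packing


def _pack_shapes(spec: ModelSpec, M: int) -> list[tuple[str, int]]:
    B = spec.n_blocks
    shapes: list[tuple[str, int]] = []
    if spec.family != "lognormal":
        shapes += [("beta0", 1), ("beta_v", 1), ("beta", M)]
        if spec.spillover and spec.fixed_spillover:
            shapes.append(("beta_spill", M))
    shapes += [("log_sd", 2 * B), ("atanh_rho", B)]
    if spec.family == "lognormal":
        shapes.append(("log_sigma", 1))
    if spec.family == "zip":
        shapes.append(("zip_logit_pi", 1))
    return shapes


def _unpack(vec: np.ndarray, shapes) -> dict[str, np.ndarray]:
    out, k = {}, 0
    for name, size in shapes:
        out[name] = vec[k] if size == 1 else vec[k : k + size]
        k += size
    return out


def _beta_prior_vectors(model: MarginalModel) -> tuple[np.ndarray, np.ndarray]:
    """Prior mean and variance of the fixed-effect columns of F."""
    pr = model.spec.priors
    p = model.p
    mean = np.full(p, pr.beta.loc)
    var = np.full(p, pr.beta.scale**2)
    mean[0], var[0] = pr.beta0.loc, pr.beta0.scale**2
    return mean, var


def _log_prob_factory(model: MarginalModel, shapes):
    spec = model.spec
    pr = spec.priors
    B = spec.n_blocks
    # LKJ(eta) on a 2x2 block == (rho+1)/2 ~ Beta(eta, eta)
    lkj_const = -betaln(pr.lkj_eta, pr.lkj_eta) - (2.0 * pr.lkj_eta - 1.0) * np.log(
        2.0
    )
    beta_mean, beta_var = _beta_prior_vectors(model)
    zl = pr.zip_logit

    def log_prob(vec: np.ndarray) -> float:
        u = _unpack(vec, shapes)
        log_sd = np.asarray(u["log_sd"], dtype=float)
        z = np.asarray(u["atanh_rho"], dtype=float)
        if np.max(np.abs(log_sd)) > 20 or np.max(np.abs(z)) > 20:
            return -np.inf
        sd = np.exp(log_sd).reshape(B, 2)
        rho = np.tanh(z)
        cov = block_covariances(sd, rho)

        # priors + transform Jacobians (plain-numpy hot path)
        lp = float(
            (np.log(pr.sd_rate) - pr.sd_rate * sd).sum() + log_sd.sum()
        )
        lp += float(
            (pr.lkj_eta * np.log1p(-rho * rho)).sum() + B * lkj_const
        )

        extra: dict = {}
        if spec.family == "lognormal":
            log_sigma = float(u["log_sigma"])
            if abs(log_sigma) > 20:
                return -np.inf
            sigma = np.exp(log_sigma)
            lp += np.log(pr.sigma_rate) - pr.sigma_rate * sigma + log_sigma
            ll = model.loglik_lognormal_intbeta(sigma, cov, beta_mean, beta_var)
        else:
            beta_parts = [
                np.atleast_1d(u["beta0"]),
                np.atleast_1d(u["beta_v"]),
                np.atleast_1d(u["beta"]),
            ]
            if "beta_spill" in u:
                beta_parts.append(np.atleast_1d(u["beta_spill"]))
            beta = np.concatenate(beta_parts)
            lp += float(
                -0.5 * (((beta - beta_mean) ** 2) / beta_var).sum()
                - 0.5 * np.log(beta_var).sum()
                - 0.5 * beta.size * _LOG2PI
            )
            if spec.family == "zip":
                c = float(u["zip_logit_pi"])
                lp += (
                    -0.5 * ((c - zl.loc) / zl.scale) ** 2
                    - np.log(zl.scale)
                    - 0.5 * _LOG2PI
                )
                extra["zip_logit_pi"] = c
            ll = model.loglik_laplace(beta, cov, extra)
        total = lp + ll
        return total if np.isfinite(total) else -np.inf

    return log_prob


def _start_vector(model: MarginalModel, shapes) -> np.ndarray:
    """Cheap method-of-moments starting point."""
    bundle, spec = model.bundle, model.spec
    M = len(bundle.predictors)
    if spec.family == "lognormal":
        coef, *_ = np.linalg.lstsq(model.F, np.log(bundle.y), rcond=None)
        resid = np.log(bundle.y) - model.F @ coef
        sigma0 = max(float(resid.std()), 1e-3)
    elif spec.family == "bernoulli":
        p = float(np.clip(bundle.y.mean(), 0.02, 0.98))
        coef = np.zeros(model.p)
        coef[0] = np.log(p / (1 - p))
    else:  # zip
        coef = np.zeros(model.p)
        coef[0] = np.log(max(bundle.y.mean(), 0.05))
    parts: list[np.ndarray] = []
    for name, size in shapes:
        if name == "beta0":
            parts.append(np.array([coef[0]]))
        elif name == "beta_v":
            parts.append(np.array([coef[1]]))
        elif name == "beta":
            parts.append(coef[2 : 2 + M])
        elif name == "beta_spill":
            parts.append(coef[2 + M : 2 + 2 * M])
        elif name == "log_sd":
            parts.append(np.full(size, np.log(0.1)))
        elif name == "atanh_rho":
            parts.append(np.zeros(size))
        elif name == "log_sigma":
            parts.append(np.array([np.log(sigma0)]))
        elif name == "zip_logit_pi":
            parts.append(np.array([-2.0]))
    return np.concatenate(parts)


def _run_chains(log_prob, x0, ndim, cfg: SamplerConfig, nwalkers: int):
    """Run independent ensembles; return per-chain draws and diagnostics."""
    keep_draws = []
    acc_fractions = []
    seed_seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    moves = [
        (emcee.moves.DEMove(), 0.8),
        (emcee.moves.DESnookerMove(), 0.2),
    ]
    for c, ss in enumerate(seed_seqs):
        rng = np.random.default_rng(ss)
        init = x0[None, :] + 0.1 * rng.standard_normal((nwalkers, ndim))
        lp0 = np.array([log_prob(v) for v in init])
        bad = ~np.isfinite(lp0)
        for _ in range(20):
            if not bad.any():
                break
            init[bad] = x0[None, :] + 0.02 * rng.standard_normal(
                (int(bad.sum()), ndim)
            )
            lp0[bad] = [log_prob(v) for v in init[bad]]
            bad = ~np.isfinite(lp0)
        if bad.any():
            raise FitError("could not initialize a finite walker ensemble")
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob, moves=moves)
        # emcee uses a legacy RandomState; seed it from the chain's stream
        chain_seed = int(ss.generate_state(1, dtype=np.uint32)[0])
        sampler.random_state = np.random.RandomState(chain_seed).get_state()
        sampler.run_mcmc(init, cfg.iterations, progress=False)
        acc = float(sampler.acceptance_fraction.mean())
        acc_fractions.append(acc)
        if acc < 0.02:
            raise FitError(
                f"chain {c} stalled (mean acceptance {acc:.3f})",
                {"acceptance_fraction": acc_fractions},
            )
        ch = sampler.get_chain(discard=cfg.warmup, thin=cfg.thin)
        # (steps, walkers, ndim): interleave walkers along the draw axis so
        # stride-thinning later keeps full time coverage
        keep_draws.append(ch.reshape(-1, ndim))
    return np.stack(keep_draws), acc_fractions, seed_seqs


def fit(
    bundle: DesignMatrixBundle,
    spec: ModelSpec,
    sampler_cfg: SamplerConfig | None = None,
    n_report: int = 1000,
    n_subject_draws: int = 200,
) -> TwoTaskPosterior:
    """Sample the two-task posterior.

    Parameters
    ----------
    bundle, spec
        Design and model specification (see :func:`build_design`).
    sampler_cfg
        Chains/iterations/warmup/seed; defaults to 4 chains x 2000
        iterations (1000 warmup).
    n_report
        Per-chain size of the stored (stride-thinned) draw set.
    n_subject_draws
        Number of joint-posterior draws for which per-subject random effects
        are sampled from their conditional distribution (0 disables).

    Raises
    ------
    FitError
        If the sampler cannot be initialized or stalls (vanishing
        acceptance rate).
    """
    cfg = sampler_cfg or SamplerConfig()
    model = MarginalModel(bundle, spec)
    M = len(bundle.predictors)
    shapes = _pack_shapes(spec, M)
    ndim = sum(s for _, s in shapes)
    nwalkers = cfg.walkers or max(2 * ndim + 2, 16)
    log_prob = _log_prob_factory(model, shapes)

    x0 = _start_vector(model, shapes)
    if not np.isfinite(log_prob(x0)):
        raise FitError("log posterior not finite at the starting point")

    all_draws, acc_fractions, seed_seqs = _run_chains(
        log_prob, x0, ndim, cfg, nwalkers
    )

    # stride-thin each chain to the reporting subset
    n_kept = all_draws.shape[1]
    take = min(n_report, n_kept)
    idx = np.linspace(0, n_kept - 1, take).astype(int)
    thin = all_draws[:, idx, :]

    B = spec.n_blocks
    draws: dict[str, np.ndarray] = {}
    k = 0
    for name, size in shapes:
        block = thin[:, :, k : k + size]
        k += size
        if name == "log_sd":
            draws["sd"] = np.exp(block).reshape(*block.shape[:2], B, 2)
        elif name == "atanh_rho":
            draws["rho"] = np.tanh(block)
        elif name == "log_sigma":
            draws["sigma"] = np.exp(block[:, :, 0])
        elif size == 1:
            draws[name] = block[:, :, 0]
        else:
            draws[name] = block

    post_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(cfg.chains + 2)[-1]
    )
    if spec.family == "lognormal":
        _attach_conditional_betas(model, spec, draws, post_rng)

    rhat_values: dict[str, float] = {}
    for name, arr in draws.items():
        if arr.ndim == 2:
            rhat_values[name] = rhat(arr)
        else:
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for j in range(flat.shape[2]):
                rhat_values[f"{name}[{j}]"] = rhat(flat[:, :, j])

    b_draws = _conditional_subject_draws(
        model, spec, draws, n_subject_draws, post_rng
    )

    return TwoTaskPosterior(
        spec=spec,
        block_names=spec.block_names,
        draws=draws,
        b_draws=b_draws,
        subject_ids=bundle.subject_ids,
        rhat=rhat_values,
        meta={
            "chains": cfg.chains,
            "iterations": cfg.iterations,
            "warmup": cfg.warmup,
            "seed": cfg.seed,
            "walkers": nwalkers,
            "sampler": "ensemble MCMC (DE moves) on the marginalized posterior",
            "acceptance_fraction": acc_fractions,
            "n_obs": bundle.n_rows,
            "n_obs_u": bundle.n_rows_u,
            "n_obs_v": bundle.n_rows_v,
            "n_subjects": bundle.n_subjects,
            "session_labels": tuple(bundle.session_labels),
            "family": spec.family,
            "variant": spec.variant,
        },
    )


def _attach_conditional_betas(model, spec, draws, rng) -> None:
    """Sample fixed effects from their exact Gaussian conditional per draw."""
    beta_mean, beta_var = _beta_prior_vectors(model)
    chains, n, _B, _ = draws["sd"].shape
    p = model.p
    out = np.empty((chains, n, p))
    for c in range(chains):
        for d in range(n):
            cov = block_covariances(draws["sd"][c, d], draws["rho"][c, d])
            mean, covb = model.beta_conditional(
                float(draws["sigma"][c, d]), cov, beta_mean, beta_var
            )
            out[c, d] = rng.multivariate_normal(mean, covb, method="cholesky")
    M = len(model.bundle.predictors)
    draws["beta0"] = out[:, :, 0]
    draws["beta_v"] = out[:, :, 1]
    draws["beta"] = out[:, :, 2 : 2 + M]
    if spec.spillover and spec.fixed_spillover:
        draws["beta_spill"] = out[:, :, 2 + M : 2 + 2 * M]


def _conditional_subject_draws(
    model, spec, draws, n_subject_draws, rng
) -> np.ndarray | None:
    if n_subject_draws <= 0:
        return None
    chains, n = draws["rho"].shape[:2]
    total = chains * n
    take = min(n_subject_draws, total)
    pick = rng.choice(total, size=take, replace=False)
    B, S, q = spec.n_blocks, model.n_subjects, model.q
    M = len(model.bundle.predictors)
    out = np.empty((take, B, S, 2))
    for j, flat_idx in enumerate(pick):
        c, d = divmod(int(flat_idx), n)
        cov = block_covariances(draws["sd"][c, d], draws["rho"][c, d])
        beta_parts = [
            np.atleast_1d(draws["beta0"][c, d]),
            np.atleast_1d(draws["beta_v"][c, d]),
            np.atleast_1d(draws["beta"][c, d]),
        ]
        if "beta_spill" in draws:
            beta_parts.append(np.atleast_1d(draws["beta_spill"][c, d]))
        beta = np.concatenate(beta_parts)
        if spec.family == "lognormal":
            mean, covb = model.conditional_moments_lognormal(
                beta, float(draws["sigma"][c, d]), cov
            )
        else:
            extra = (
                {"zip_logit_pi": float(draws["zip_logit_pi"][c, d])}
                if spec.family == "zip"
                else {}
            )
            mean, covb = model.conditional_moments_laplace(beta, cov, extra)
        L = np.linalg.cholesky(covb)
        z = rng.standard_normal((S, q))
        b = mean + np.einsum("sqr,sr->sq", L, z)
        out[j] = b.reshape(S, B, 2).transpose(1, 0, 2)
    return out
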