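"""Random-effect-marginalized likelihoods used by the sampler.

The joint posterior of the two-task model contains 2 x (M + 1) random effects
per subject.  Sampling that space directly is wasteful: conditional on the
variance parameters the random effects are (for the lognormal family) exactly
Gaussian, so they can be integrated out analytically.  With
``log y_i ~ N(F_i beta + Z_i b_i, sigma^2 I)`` and ``b_i ~ N(0, G)`` (G block
diagonal with one 2x2 covariance per predictor), the marginal covariance is
``sigma^2 I + Z_i G Z_i'`` and the Woodbury/matrix-determinant identities
reduce each likelihood evaluation to q x q linear algebra per subject
(q = 2 x number of blocks), independent of the number of words.

For the Bernoulli and zero-inflated-Poisson families the integral has no
closed form; it is approximated by a per-subject Laplace approximation around
the conditional mode (the approach of glmmTMB/INLA-style fitters).

The per-subject conditional distribution of the random effects given the
variance parameters is Gaussian in both cases (exactly for lognormal, as the
Laplace Gaussian otherwise) and is used to attach per-subject effect draws to
the posterior.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

from .design import DesignMatrixBundle
from .spec import ModelSpec

__all__ = ["MarginalModel", "block_covariances"]

_LOG2PI = np.log(2.0 * np.pi)


def block_covariances(sd: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Stack of 2x2 covariance blocks from per-block sds and correlations."""
    sd = np.asarray(sd, dtype=float)
    rho = np.asarray(rho, dtype=float)
    off = rho * sd[:, 0] * sd[:, 1]
    out = np.empty((sd.shape[0], 2, 2))
    out[:, 0, 0] = sd[:, 0] ** 2
    out[:, 1, 1] = sd[:, 1] ** 2
    out[:, 0, 1] = out[:, 1, 0] = off
    return out


def _blockdiag_inverse(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log determinant of a block-diagonal (B,2,2) covariance."""
    det = cov[:, 0, 0] * cov[:, 1, 1] - cov[:, 0, 1] ** 2
    if (det <= 0).any() or (np.diagonal(cov, axis1=1, axis2=2) <= 0).any():
        raise np.linalg.LinAlgError("non-PD random-effect block")
    inv = np.empty_like(cov)
    inv[:, 0, 0] = cov[:, 1, 1] / det
    inv[:, 1, 1] = cov[:, 0, 0] / det
    inv[:, 0, 1] = inv[:, 1, 0] = -cov[:, 0, 1] / det
    B = cov.shape[0]
    q = 2 * B
    G = np.zeros((q, q))
    for b in range(B):
        G[2 * b : 2 * b + 2, 2 * b : 2 * b + 2] = inv[b]
    return G, float(np.log(det).sum())


class MarginalModel:
    """Precomputed design products for fast marginal-likelihood evaluation."""

    def __init__(self, bundle: DesignMatrixBundle, spec: ModelSpec):
        if bundle.X_lag is None and spec.spillover:
            raise ValueError("spec has spillover but bundle has no lags")
        self.bundle = bundle
        self.spec = spec
        self.n_blocks = spec.n_blocks
        self.q = 2 * self.n_blocks
        M = len(bundle.predictors)

        delta_u = 1.0 - bundle.delta_v
        fcols = [np.ones(bundle.n_rows), bundle.delta_v]
        fcols += [bundle.X[:, m] for m in range(M)]
        if spec.spillover and spec.fixed_spillover:
            fcols += [bundle.X_lag[:, m] for m in range(M)]
        self.F = np.column_stack(fcols)
        self.p = self.F.shape[1]

        zbase = [np.ones(bundle.n_rows)]
        zbase += [bundle.X[:, m] for m in range(M)]
        if spec.spillover:
            zbase += [bundle.X_lag[:, m] for m in range(M)]
        zcols = []
        for col in zbase:
            zcols.append(col * delta_u)
            zcols.append(col * bundle.delta_v)
        self.Z = np.column_stack(zcols)  # (n, q)

        # per-subject row segments (bundle rows are subject-sorted)
        idx = bundle.subject_idx
        if (np.diff(idx) < 0).any():
            raise ValueError("bundle rows must be sorted by subject")
        self.n_subjects = bundle.n_subjects
        self.starts = np.searchsorted(idx, np.arange(self.n_subjects))
        self.counts = np.bincount(idx, minlength=self.n_subjects).astype(float)

        self.ZtZ = self._segment_outer(self.Z, self.Z)
        self.ZtF = self._segment_outer(self.Z, self.F)
        if spec.family == "lognormal":
            ly = np.log(bundle.y)
            self.Zty = self._segment_matvec(self.Z, ly)
            self.Fty_tot = self.F.T @ ly
            self.FtF_tot = self.F.T @ self.F
            self.yy_tot = float(ly @ ly)
            self.sum_logy = float(ly.sum())  # lognormal Jacobian term
        self.n_total = float(bundle.n_rows)

    # -- segment helpers ---------------------------------------------------
    def _segment_outer(self, A: np.ndarray, Bm: np.ndarray) -> np.ndarray:
        prod = A[:, :, None] * Bm[:, None, :]
        return np.add.reduceat(prod, self.starts, axis=0)

    def _segment_matvec(self, A: np.ndarray, v: np.ndarray) -> np.ndarray:
        return np.add.reduceat(A * v[:, None], self.starts, axis=0)

    def _segment_sum(self, v: np.ndarray) -> np.ndarray:
        return np.add.reduceat(v, self.starts, axis=0)

    # -- lognormal: exact marginal ----------------------------------------
    def loglik_lognormal(self, beta: np.ndarray, sigma: float,
                         cov_blocks: np.ndarray) -> float:
        """Exact marginal log likelihood (random effects integrated out)."""
        if sigma <= 0:
            return -np.inf
        try:
            Ginv, logdetG = _blockdiag_inverse(cov_blocks)
        except np.linalg.LinAlgError:
            return -np.inf
        s2 = sigma * sigma
        C = Ginv[None] + self.ZtZ / s2
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetC = 2.0 * np.log(
            np.diagonal(L, axis1=1, axis2=2)
        ).sum()
        Ztr = self.Zty - self.ZtF @ beta  # (S, q)
        sol = np.linalg.solve(C, Ztr[..., None])[..., 0]
        quad_corr = np.einsum("sq,sq->", Ztr, sol) / (s2 * s2)
        rr = (
            self.yy_tot
            - 2.0 * beta @ self.Fty_tot
            + beta @ self.FtF_tot @ beta
        )
        return float(
            -0.5
            * (
                self.n_total * (_LOG2PI + np.log(s2))
                + self.n_subjects * logdetG
                + logdetC
                + rr / s2
                - quad_corr
            )
            - self.sum_logy
        )

    def _woodbury_products(self, sigma: float, cov_blocks: np.ndarray):
        """Shared pieces of V^-1 = (sigma^2 I + Z G Z')^-1 per subject."""
        Ginv, logdetG = _blockdiag_inverse(cov_blocks)
        s2 = sigma * sigma
        C = Ginv[None] + self.ZtZ / s2
        L = np.linalg.cholesky(C)  # raises LinAlgError if not PD
        logdetC = float(2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
        logdetV = (
            self.n_total * np.log(s2) + self.n_subjects * logdetG + logdetC
        )
        K = np.linalg.solve(C, self.ZtF)  # (S, q, p)
        Cy = np.linalg.solve(C, self.Zty[..., None])[..., 0]  # (S, q)
        s4 = s2 * s2
        FVF = self.FtF_tot / s2 - np.einsum("sqp,sqr->pr", self.ZtF, K) / s4
        FVy = self.Fty_tot / s2 - np.einsum("sqp,sq->p", self.ZtF, Cy) / s4
        yVy = self.yy_tot / s2 - np.einsum("sq,sq->", self.Zty, Cy) / s4
        return FVF, FVy, float(yVy), logdetV

    def loglik_lognormal_intbeta(
        self,
        sigma: float,
        cov_blocks: np.ndarray,
        beta_prior_mean: np.ndarray,
        beta_prior_var: np.ndarray,
    ) -> float:
        """Marginal log likelihood with *both* b and beta integrated out.

        The Gaussian prior on the fixed effects (diagonal covariance
        ``beta_prior_var``) is conjugate given the variance parameters, so
        the fixed effects can be collapsed as well; the sampler then only
        explores sds, correlations and sigma.
        """
        if sigma <= 0:
            return -np.inf
        try:
            FVF, FVy, yVy, logdetV = self._woodbury_products(sigma, cov_blocks)
        except np.linalg.LinAlgError:
            return -np.inf
        Pinv = np.diag(1.0 / beta_prior_var)
        A = FVF + Pinv
        try:
            La = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetA = float(2.0 * np.log(np.diag(La)).sum())
        b0 = beta_prior_mean
        g = FVy - FVF @ b0
        sol = np.linalg.solve(A, g)
        quad = (
            yVy - 2.0 * b0 @ FVy + b0 @ FVF @ b0 - g @ sol
        )
        return float(
            -0.5
            * (
                self.n_total * _LOG2PI
                + logdetV
                + np.log(beta_prior_var).sum()
                + logdetA
                + quad
            )
            - self.sum_logy
        )

    def beta_conditional(
        self,
        sigma: float,
        cov_blocks: np.ndarray,
        beta_prior_mean: np.ndarray,
        beta_prior_var: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Gaussian conditional of the fixed effects given variance params."""
        FVF, FVy, _, _ = self._woodbury_products(sigma, cov_blocks)
        Pinv = np.diag(1.0 / beta_prior_var)
        A = FVF + Pinv
        mean = np.linalg.solve(A, FVy + beta_prior_mean / beta_prior_var)
        return mean, np.linalg.inv(A)

    def conditional_moments_lognormal(
        self, beta: np.ndarray, sigma: float, cov_blocks: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject mean and covariance of b_i given data and parameters."""
        Ginv, _ = _blockdiag_inverse(cov_blocks)
        s2 = sigma * sigma
        C = Ginv[None] + self.ZtZ / s2
        Ztr = self.Zty - self.ZtF @ beta
        mean = np.linalg.solve(C, Ztr[..., None])[..., 0] / s2
        cov = np.linalg.inv(C)
        return mean, cov

    # -- glm families: Laplace approximation --------------------------------
    def _glm_derivs(self, theta: np.ndarray, extra: dict):
        """Per-observation loglik, first and (negated) second derivative."""
        y = self.bundle.y
        fam = self.spec.family
        if fam == "bernoulli":
            p = expit(theta)
            ll = y * theta - np.logaddexp(0.0, theta)
            return ll, y - p, p * (1.0 - p)
        if fam == "zip":
            c = extra["zip_logit_pi"]
            log_pi = -np.logaddexp(0.0, -c)
            log_1mpi = -np.logaddexp(0.0, c)
            lam = np.exp(np.clip(theta, -30, 30))
            zero_mask = y == 0
            ll = np.where(
                zero_mask,
                np.logaddexp(log_pi, log_1mpi - lam),
                log_1mpi + y * theta - lam - gammaln(y + 1.0),
            )
            # y > 0: d l / d theta = y - lam ; d2 = -lam
            g = y - lam
            w = lam.copy()
            # y == 0: l = log(pi + (1-pi) exp(-lam))
            a = np.exp(log_1mpi - lam)  # (1-pi) e^-lam
            p0 = np.exp(log_pi) + a
            g0 = -lam * a / p0
            w0 = lam * a * (1.0 - lam) / p0 + (lam * a / p0) ** 2
            g = np.where(zero_mask, g0, g)
            w = np.where(zero_mask, w0, w)
            return ll, g, w
        raise ValueError(f"no Laplace derivatives for family {fam!r}")

    def _glm_objective(self, b_flat: np.ndarray, beta: np.ndarray,
                       Ginv: np.ndarray, extra: dict):
        """Per-subject h_i(b_i) = loglik_i + Gaussian exponent, plus derivs."""
        theta = self.F @ beta + np.einsum(
            "nq,nq->n", self.Z, b_flat[self.bundle.subject_idx]
        )
        ll, g, w = self._glm_derivs(theta, extra)
        h = self._segment_sum(ll) - 0.5 * np.einsum(
            "sq,qr,sr->s", b_flat, Ginv, b_flat
        )
        grad = self._segment_matvec(self.Z, g) - b_flat @ Ginv
        hess = -self._segment_outer(self.Z * w[:, None], self.Z) - Ginv[None]
        return h, grad, hess

    def loglik_laplace(self, beta: np.ndarray, cov_blocks: np.ndarray,
                       extra: dict, max_iter: int = 50,
                       tol: float = 1e-8) -> float:
        mode, h, hess, ok = self._laplace_mode(
            beta, cov_blocks, extra, max_iter, tol
        )
        if not ok:
            return -np.inf
        _, logdetG = _blockdiag_inverse(cov_blocks)
        sign, logdet_negH = np.linalg.slogdet(-hess)
        if (sign <= 0).any():
            return -np.inf
        # q/2 log 2pi terms of the Gaussian prior and the Laplace integral
        # cancel exactly
        return float(
            h.sum() - 0.5 * self.n_subjects * logdetG - 0.5 * logdet_negH.sum()
        )

    def _laplace_mode(self, beta, cov_blocks, extra, max_iter=50, tol=1e-8):
        try:
            Ginv, _ = _blockdiag_inverse(cov_blocks)
        except np.linalg.LinAlgError:
            return None, None, None, False
        S, q = self.n_subjects, self.q
        b = np.zeros((S, q))
        h, grad, hess = self._glm_objective(b, beta, Ginv, extra)
        for _ in range(max_iter):
            if np.max(np.abs(grad)) < tol:
                break
            step = np.linalg.solve(-hess, grad[..., None])[..., 0]
            # damped Newton: per-subject step halving
            scale = np.ones(S)
            for _ in range(12):
                b_new = b + scale[:, None] * step
                h_new, grad_new, hess_new = self._glm_objective(
                    b_new, beta, Ginv, extra
                )
                worse = h_new < h - 1e-12
                if not worse.any():
                    break
                scale[worse] *= 0.5
            b, h, grad, hess = b_new, h_new, grad_new, hess_new
        if not np.isfinite(h).all():
            return None, None, None, False
        return b, h, hess, True

    def conditional_moments_laplace(self, beta, cov_blocks, extra):
        """Laplace-Gaussian conditional moments of b_i per subject."""
        mode, _, hess, ok = self._laplace_mode(beta, cov_blocks, extra)
        if not ok:
            raise np.linalg.LinAlgError("Laplace mode finding failed")
        cov = np.linalg.inv(-hess)
        return mode, cov
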