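"""Reliability-paradox simulator and closed-form correlation attenuation.

An experimental effect can replicate robustly at the population level while the
per-subject effect estimates barely correlate across two sessions.  The driver
is the ratio of measurement-error variance to true between-subjects variance:
with observed estimates ``x = x* + eps_x`` and ``y = y* + eps_y`` (independent
additive errors), the population correlation of the observed estimates is the
true correlation shrunk by Spearman's disattenuation factor,

    rho = rho* / sqrt((1 + s2_ex / s2_x*) (1 + s2_ey / s2_y*)).

This module simulates the paired two-session design (each per-subject estimate
being the mean of ``M`` noisy trials, so its error variance is the per-trial
error variance divided by ``M``) and provides the closed forms to compare
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SimulationConfig",
    "PairedEstimates",
    "simulate_two_sessions",
    "pearson",
    "expected_attenuation",
    "snr_attenuation",
    "replicate_correlations",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-session true-effect-plus-error model.

    Attributes
    ----------
    n_subjects
        Number of subjects N (>= 3).
    mu
        True mean effect, shared by both sessions.
    var_true_x, var_true_y
        True between-subjects variances of the session-1 and session-2
        effects (> 0).
    rho_true
        True cross-session correlation of the subject-level effects,
        in [-1, 1].
    err_sd_trial
        Standard deviation of the additive measurement error of a *single
        trial* (>= 0).  A per-subject estimate averaged over ``n_trials``
        trials has error variance ``err_sd_trial**2 / n_trials``.
    n_trials
        Trials per subject per session, M (>= 1).
    seed
        Seed for the simulation RNG.
    """

    n_subjects: int = 100
    mu: float = 10.0
    var_true_x: float = 80.0
    var_true_y: float = 80.0
    rho_true: float = 0.95
    err_sd_trial: float = 5.0
    n_trials: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.var_true_x <= 0 or self.var_true_y <= 0:
            raise ValueError("true variances must be > 0")
        if not -1.0 <= self.rho_true <= 1.0:
            raise ValueError("rho_true must lie in [-1, 1]")
        if self.err_sd_trial < 0:
            raise ValueError("err_sd_trial must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def covariance(self) -> np.ndarray:
        """2x2 covariance matrix of the true effect pair (x*, y*)."""
        cov_xy = self.rho_true * np.sqrt(self.var_true_x * self.var_true_y)
        return np.array(
            [[self.var_true_x, cov_xy], [cov_xy, self.var_true_y]]
        )

    @property
    def err_var_estimate(self) -> float:
        """Error variance of an M-trial mean estimate."""
        return self.err_sd_trial**2 / self.n_trials


@dataclass(frozen=True)
class PairedEstimates:
    """Per-subject observed effect estimates from the two sessions."""

    x: np.ndarray
    y: np.ndarray
    truth_x: np.ndarray | None = field(default=None, repr=False)
    truth_y: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("estimates must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.x.size


def simulate_two_sessions(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> PairedEstimates:
    """Draw paired two-session effect estimates under additive error.

    True pairs (x*, y*) come from the bivariate normal with mean (mu, mu)
    and the configured covariance; each observed estimate is the mean of
    ``n_trials`` independent noisy trials, i.e. the true value plus Gaussian
    error with variance ``err_sd_trial**2 / n_trials``, independently per
    session.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cov = config.covariance
    # Guard against numerically non-PSD input (|rho| slightly above 1 is
    # already rejected by the config; this catches degenerate variances).
    if np.linalg.eigvalsh(cov).min() < -1e-10 * max(
        config.var_true_x, config.var_true_y
    ):
        raise ValueError("covariance matrix is not positive semi-definite")
    mean = np.array([config.mu, config.mu])
    truth = rng.multivariate_normal(mean, cov, size=config.n_subjects)
    err_sd = config.err_sd_trial / np.sqrt(config.n_trials)
    noise = rng.normal(0.0, err_sd, size=(config.n_subjects, 2))
    observed = truth + noise
    return PairedEstimates(
        x=observed[:, 0],
        y=observed[:, 1],
        truth_x=truth[:, 0],
        truth_y=truth[:, 1],
    )


def pearson(pairs: PairedEstimates) -> float:
    """Sample Pearson correlation of the paired estimates.

    Raises
    ------
    ValueError
        If fewer than 3 pairs are available or either array is constant
        (the correlation is undefined).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(pairs.x) == 0 or np.ptp(pairs.y) == 0:
        raise ValueError("correlation undefined for a constant array")
    return float(stats.pearsonr(pairs.x, pairs.y).statistic)


def expected_attenuation(
    rho_true: float,
    var_true_x: float,
    var_true_y: float,
    err_var_x: float,
    err_var_y: float,
) -> float:
    """Population correlation of error-contaminated estimates (Spearman).

    ``err_var_x`` / ``err_var_y`` are the error variances of the *per-subject
    estimates*; for estimates averaged over M trials pass the per-trial error
    variance divided by M.
    """
    if var_true_x <= 0 or var_true_y <= 0:
        raise ValueError("true variances must be > 0")
    if err_var_x < 0 or err_var_y < 0:
        raise ValueError("error variances must be >= 0")
    shrink = np.sqrt(
        (1.0 + err_var_x / var_true_x) * (1.0 + err_var_y / var_true_y)
    )
    return float(rho_true / shrink)


def snr_attenuation(rho_true: float, gamma2: float, n_trials: int) -> float:
    """Attenuated correlation in the symmetric-sessions, M-trial-mean case.

    ``gamma2`` is the per-trial noise-to-signal variance ratio
    ``err_sd_trial**2 / var_true``; with both sessions sharing it, the
    observed correlation is ``rho_true / (1 + gamma2 / M)``.  Identical to
    :func:`expected_attenuation` with symmetric arguments and estimate-level
    error variance ``gamma2 / M``.
    """
    if gamma2 < 0:
        raise ValueError("gamma2 must be >= 0")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return float(rho_true / (1.0 + gamma2 / n_trials))


def replicate_correlations(
    config: SimulationConfig, replicates: int, seed: int | None = None
) -> np.ndarray:
    """Observed Pearson correlations over independent simulation replicates."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return np.array(
        [pearson(simulate_two_sessions(config, rng)) for _ in range(replicates)]
    )
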