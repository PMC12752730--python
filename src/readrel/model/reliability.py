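"""Reliability summaries from the posterior correlation draws.

Reliability of an individual-level effect is the posterior of the
cross-session (or cross-method) correlation of the per-subject random
effects for that predictor.  A predictor is flagged reliable when the
central 95% credible interval of the correlation excludes zero; qualitative
bands follow documented convention cutoffs (poor < 0.3 <= low < 0.5 <=
moderate < 0.7 <= strong), configurable by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReliabilitySummary", "extract_reliability", "qualitative_band"]

DEFAULT_BAND_CUTOFFS = (0.3, 0.5, 0.7)
BAND_NAMES = ("poor", "low", "moderate", "strong")


def qualitative_band(
    value: float, cutoffs: tuple[float, float, float] = DEFAULT_BAND_CUTOFFS
) -> str:
    """Verbal reliability band of a correlation point estimate."""
    lo, mid, hi = cutoffs
    if value < lo:
        return "poor"
    if value < mid:
        return "low"
    if value < hi:
        return "moderate"
    return "strong"


@dataclass(frozen=True)
class ReliabilitySummary:
    """Posterior summary of one reliability correlation."""

    predictor: str
    mean: float
    cri_lower: float
    cri_upper: float
    excludes_zero: bool
    band: str

    def __post_init__(self) -> None:
        if not self.cri_lower <= self.mean <= self.cri_upper:
            raise ValueError("credible interval must contain the mean")


def extract_reliability(
    posterior,
    predictor: str,
    prob: float = 0.95,
    cutoffs: tuple[float, float, float] = DEFAULT_BAND_CUTOFFS,
) -> ReliabilitySummary:
    """Summarize the correlation draws of one random-effect block.

    ``predictor`` is a predictor name, ``"intercept"``, or a lagged name
    like ``"surp_prev"`` in spillover fits.
    """
    if not 0 < prob < 1:
        raise ValueError("prob must lie in (0, 1)")
    draws = posterior.rho_draws(predictor)
    alpha = (1.0 - prob) / 2.0
    lower, upper = np.quantile(draws, [alpha, 1.0 - alpha])
    mean = float(draws.mean())
    return ReliabilitySummary(
        predictor=predictor,
        mean=mean,
        cri_lower=float(lower),
        cri_upper=float(upper),
        excludes_zero=bool(lower > 0.0 or upper < 0.0),
        band=qualitative_band(mean, cutoffs),
    )
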