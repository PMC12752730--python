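"""Split-R-hat convergence diagnostic."""

from __future__ import annotations

import numpy as np

__all__ = ["rhat"]


def rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a scalar parameter.

    Parameters
    ----------
    chains
        Array of shape (n_chains, n_draws).  Each chain is split in half, so
        stationarity within a chain inflates the statistic as well.

    Returns
    -------
    The potential-scale-reduction factor; ~1 for well-mixed chains.  By
    convention 1.0 is returned when all draws are identical (zero variance).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    m, n = arr.shape
    if n < 4:
        raise ValueError("need at least 4 draws per chain to split")
    half = n // 2
    split = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m2, n2 = split.shape
    within = split.var(axis=1, ddof=1)
    W = within.mean()
    if W == 0:
        return 1.0
    means = split.mean(axis=1)
    Bn = n2 * means.var(ddof=1)
    var_hat = (n2 - 1) / n2 * W + Bn / n2
    return float(np.sqrt(var_hat / W))
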