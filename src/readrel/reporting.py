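"""Variance decomposition, natural-scale back-transforms and report tables.

The signal-to-noise ratio of an individual-level effect is
``gamma_m = sd_m / sigma``: the between-subjects sd of the effect divided by
the residual (trial-by-trial) sd.  Together with the number of trials per
subject it governs how strongly the observed cross-session correlation of
the effect is attenuated relative to its true reliability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .model.fit import TwoTaskPosterior
from .model.reliability import ReliabilitySummary

__all__ = [
    "VarianceDecomposition",
    "decompose_variance",
    "back_transform",
    "reliability_report",
]


@dataclass(frozen=True)
class VarianceDecomposition:
    """Posterior-mean variance components, one row per session.

    ``table`` has columns ``session``, ``sigma``, then for every
    random-effect block ``sd_<block>`` and ``gamma_<block>`` (the ratio
    sd/sigma computed from the reported point estimates), plus ``n_obs``
    and ``n_ind``.
    """

    table: pd.DataFrame
    block_names: tuple[str, ...]


def decompose_variance(posterior: TwoTaskPosterior) -> VarianceDecomposition:
    """Posterior means of sigma, per-block between-subjects sds, and ratios.

    Only defined for the continuous (lognormal) family, where the residual
    sd sigma exists.
    """
    if posterior.spec.family != "lognormal":
        raise ValueError(
            "variance decomposition requires a continuous-family posterior"
        )
    sigma_hat = float(posterior.flat("sigma").mean())
    sd_hat = posterior.flat("sd").mean(axis=0)  # (B, 2)
    rows = []
    for s, label in enumerate(posterior.meta.get("session_labels", ("u", "v"))):
        row: dict = {"session": label, "sigma": sigma_hat}
        for b, name in enumerate(posterior.block_names):
            row[f"sd_{name}"] = float(sd_hat[b, s])
            row[f"gamma_{name}"] = float(sd_hat[b, s] / sigma_hat)
        row["n_obs"] = posterior.meta.get(
            "n_obs_u" if s == 0 else "n_obs_v", np.nan
        )
        row["n_ind"] = posterior.meta.get("n_subjects", np.nan)
        rows.append(row)
    return VarianceDecomposition(
        table=pd.DataFrame(rows), block_names=posterior.block_names
    )


def back_transform(family: str, value: float):
    """Map a linear-predictor-scale value to the natural response scale.

    lognormal (log-ms location) -> ms via exp; bernoulli (logit) ->
    probability via the inverse logit; zip (log rate) -> rate via exp.
    ``"log"`` and ``"logit"`` are accepted as scale aliases.
    """
    value = np.asarray(value, dtype=float)
    if family in ("lognormal", "zip", "log"):
        out = np.exp(value)
    elif family in ("bernoulli", "logit"):
        out = expit(value)
    else:
        raise ValueError(f"unknown family or scale {family!r}")
    return float(out) if out.ndim == 0 else out


def reliability_report(
    summaries: list[ReliabilitySummary],
    decomposition: VarianceDecomposition | None = None,
    out_dir=None,
) -> dict:
    """Render reliability (and optionally variance) tables.

    Returns a dict with the assembled DataFrames; when ``out_dir`` is given,
    also writes ``reliability.csv``, ``variance_decomposition.csv`` and a
    human-readable ``report.md`` (reliable effects — 95% CrI excluding 0 —
    are flagged and shown in bold).
    """
    rel = pd.DataFrame(
        [
            {
                "predictor": s.predictor,
                "mean": s.mean,
                "cri_lower": s.cri_lower,
                "cri_upper": s.cri_upper,
                "excludes_zero": s.excludes_zero,
                "band": s.band,
            }
            for s in summaries
        ]
    )
    out = {"reliability": rel}
    if decomposition is not None:
        out["variance_decomposition"] = decomposition.table

    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        rel.to_csv(out_path / "reliability.csv", index=False)
        lines = ["# Reliability report", "", "## Reliability of individual effects", ""]
        if len(rel):
            lines.append("| Predictor | rho (95% CrI) | Reliable | Band |")
            lines.append("|---|---|---|---|")
            for s in summaries:
                est = f"{s.mean:.2f} [{s.cri_lower:.2f}, {s.cri_upper:.2f}]"
                if s.excludes_zero:
                    est = f"**{est}**"
                lines.append(
                    f"| {s.predictor} | {est} | "
                    f"{'yes' if s.excludes_zero else 'no'} | {s.band} |"
                )
        else:
            lines.append("(no reliability summaries)")
        if decomposition is not None:
            decomposition.table.to_csv(
                out_path / "variance_decomposition.csv", index=False
            )
            lines += ["", "## Variance decomposition", ""]
            lines.append("```")
            lines.append(decomposition.table.to_string(index=False))
            lines.append("```")
        (out_path / "report.md").write_text("\n".join(lines) + "\n")
        out["paths"] = {
            "reliability": str(out_path / "reliability.csv"),
            "report": str(out_path / "report.md"),
        }
        if decomposition is not None:
            out["paths"]["variance_decomposition"] = str(
                out_path / "variance_decomposition.csv"
            )
    return out
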