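"""Synthetic naturalistic-reading corpora with known ground truth.

The generator emulates the structure of a two-session (or two-method)
naturalistic reading study: each subject reads a few thousand words per
session; every word carries five correlated psycholinguistic predictors
(word length, log lemma frequency, surprisal, dependency distance, number of
left dependents); responses are word-level reading measures drawn from a
lognormal, Bernoulli or zero-inflated-Poisson observation model whose linear
predictor contains population-level effects plus per-subject-per-session
random intercepts and slopes with a specified cross-session correlation —
the ground-truth reliability that model fitting should recover.

Defaults are sized for desk-scale experimentation (40 subjects x 2 sessions
x 500 words); :func:`full_scale_config` mirrors the scale of a real corpus
(131 subjects, ~2233 words per session).  All randomness flows from a single
seed through ``numpy.random.SeedSequence`` spawning, so every artifact is
reproducible bit-for-bit from (seed, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .measures import FixationSequence, WordMeasures
from .model.design import DesignMatrixBundle
from .model.likelihood import linear_predictor

__all__ = [
    "PREDICTORS",
    "EffectSpec",
    "CorpusConfig",
    "default_effect_specs",
    "default_predictor_correlation",
    "full_scale_config",
    "generate_predictors",
    "sample_random_effects",
    "simulate_responses",
    "generate_scanpath",
    "write_corpus",
]

PREDICTORS = ("wl", "freq", "surp", "depdist", "nleftdep")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth parameters of one individual-level effect.

    ``beta`` is the population-level effect of the (z-scored) predictor;
    ``sd_u``/``sd_v`` the between-subjects sds of the individual effect in
    the two sessions; ``rho`` their cross-session correlation — the true
    reliability the fitted model should recover.
    """

    name: str
    beta: float
    sd_u: float
    sd_v: float
    rho: float

    def __post_init__(self) -> None:
        if self.sd_u < 0 or self.sd_v < 0:
            raise ValueError("random-effect sds must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")


def default_effect_specs() -> tuple[EffectSpec, ...]:
    """Plausibility-based defaults on the log-ms scale.

    Magnitudes echo what hierarchical fits of naturalistic reading data
    typically report: a large, highly reliable random intercept; a small but
    reliable word-length slope; progressively weaker and less reliable
    higher-level effects.
    """
    return (
        EffectSpec("intercept", 0.0, 0.25, 0.25, 0.75),
        EffectSpec("wl", 0.05, 0.05, 0.05, 0.75),
        EffectSpec("freq", -0.04, 0.03, 0.03, 0.50),
        EffectSpec("surp", 0.03, 0.02, 0.02, 0.25),
        EffectSpec("depdist", 0.01, 0.02, 0.02, 0.60),
        EffectSpec("nleftdep", 0.01, 0.02, 0.02, 0.45),
    )


def default_predictor_correlation() -> np.ndarray:
    """Latent correlation among the five predictors.

    Length, frequency and surprisal are strongly intercorrelated in real
    text (long words are rare and surprising); the dependency features are
    only weakly related to the lexical ones.
    """
    return np.array(
        [
            #  wl    freq  surp  depd  nleft
            [1.00, -0.60, 0.50, 0.10, 0.10],
            [-0.60, 1.00, -0.50, 0.00, 0.00],
            [0.50, -0.50, 1.00, 0.10, 0.00],
            [0.10, 0.00, 0.10, 1.00, 0.20],
            [0.10, 0.00, 0.00, 0.20, 1.00],
        ]
    )


@dataclass(frozen=True)
class CorpusConfig:
    """Generative settings of one synthetic corpus."""

    n_subjects: int = 40
    words_per_session: tuple[int, int] = (500, 500)
    family: str = "lognormal"
    beta0: float = 5.5
    session_effect: float = -0.02
    sigma: float | None = 0.44
    zip_zero_prob: float | None = None
    effect_specs: tuple[EffectSpec, ...] = field(
        default_factory=default_effect_specs
    )
    spillover_specs: tuple[EffectSpec, ...] = ()
    predictor_correlation: np.ndarray | None = None
    screen_size: int = 50
    methods: tuple[str, str] = ("et", "et")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "bernoulli", "zip"):
            raise ValueError(f"unknown family {self.family!r}")
        if min(self.words_per_session) < 2:
            raise ValueError("words_per_session must be >= 2")
        if self.family == "lognormal":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("lognormal family needs sigma > 0")
        elif self.sigma is not None:
            raise ValueError(f"sigma is undefined for the {self.family} family")
        if self.family == "zip":
            if self.zip_zero_prob is None or not 0 <= self.zip_zero_prob < 1:
                raise ValueError("zip family needs zip_zero_prob in [0, 1)")
        elif self.zip_zero_prob is not None:
            raise ValueError("zip_zero_prob is only valid for the zip family")
        names = [s.name for s in self.effect_specs]
        if "intercept" not in names:
            raise ValueError("effect_specs must include an 'intercept' entry")
        if len(set(names)) != len(names):
            raise ValueError("duplicate effect-spec names")

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.effect_specs if s.name != "intercept")


def full_scale_config(**overrides) -> CorpusConfig:
    """Preset at the scale of a real two-session corpus (not used in tests)."""
    base = CorpusConfig(n_subjects=131, words_per_session=(2233, 2233))
    return replace(base, **overrides)


def _marginal_transforms(latent: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Map latent standard-normal columns to plausible predictor marginals."""
    z = {name: latent[:, k] for k, name in enumerate(PREDICTORS)}
    n = latent.shape[0]
    wl = np.clip(np.round(np.exp(1.45 + 0.45 * z["wl"])), 1, 20)
    freq = 4.0 + 1.2 * z["freq"]  # Zipf-like log lemma frequency
    surp = np.exp(1.8 + 0.55 * z["surp"])  # positive, right-skewed bits
    # dependency distance: defined only for (head-initial) dependents
    dep_mask = rng.random(n) < 0.6
    depdist = np.round(np.exp(0.7 + 0.7 * z["depdist"]))
    depdist = np.where(dep_mask, np.maximum(depdist, 0.0), np.nan)
    # number of left dependents: defined on heads only, small counts
    head_mask = rng.random(n) < 0.45
    nleft = np.clip(np.round(np.exp(0.35 + 0.55 * z["nleftdep"]) - 1.0), 0, 6)
    nleft = np.where(head_mask, nleft, np.nan)
    return pd.DataFrame(
        {"wl": wl, "freq": freq, "surp": surp, "depdist": depdist,
         "nleftdep": nleft}
    )


def _zscore_with_missing(col: np.ndarray) -> np.ndarray:
    """Z-score over defined entries; undefined entries map to the mean (0)."""
    defined = np.isfinite(col)
    mu = col[defined].mean()
    sd = col[defined].std(ddof=0)
    if sd == 0:
        raise ValueError("constant predictor column")
    out = np.zeros_like(col, dtype=float)
    out[defined] = (col[defined] - mu) / sd
    return out


def generate_predictors(
    n_words: int,
    predictor_correlation: np.ndarray | None = None,
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Correlated word-level predictors with raw and z-scored columns.

    Raw columns keep NaN where a predictor is undefined (non-dependents /
    non-heads); the ``*_z`` columns set those words to the predictor mean,
    i.e. zero after standardization, so no rows need dropping downstream.
    """
    if n_words < 2:
        raise ValueError("n_words must be >= 2")
    corr = (
        default_predictor_correlation()
        if predictor_correlation is None
        else np.asarray(predictor_correlation, dtype=float)
    )
    if corr.shape != (len(PREDICTORS), len(PREDICTORS)):
        raise ValueError("predictor_correlation must be 5x5")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("predictor correlation is not positive definite") from err
    if rng is None:
        rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_words, len(PREDICTORS))) @ chol.T
    df = _marginal_transforms(latent, rng)
    for name in PREDICTORS:
        df[f"{name}_z"] = _zscore_with_missing(df[name].to_numpy())
    return df


def sample_random_effects(
    n_subjects: int,
    effect_specs: tuple[EffectSpec, ...],
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Per-subject (session-u, session-v) effects, one (N, 2) array per spec.

    Blocks for different effects are mutually independent (the model's
    block-diagonal random-effect structure).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for s in effect_specs:
        cov = np.array(
            [
                [s.sd_u**2, s.rho * s.sd_u * s.sd_v],
                [s.rho * s.sd_u * s.sd_v, s.sd_v**2],
            ]
        )
        # allow degenerate (sd = 0 or |rho| = 1) blocks
        out[s.name] = rng.multivariate_normal(
            np.zeros(2), cov, size=n_subjects, method="svd"
        )
    return out


def _sample_family(theta, config: CorpusConfig, rng) -> np.ndarray:
    if config.family == "lognormal":
        return np.exp(rng.normal(theta, config.sigma))
    if config.family == "bernoulli":
        return rng.binomial(1, 1.0 / (1.0 + np.exp(-theta))).astype(float)
    counts = rng.poisson(np.exp(theta)).astype(float)
    zero = rng.random(theta.size) < config.zip_zero_prob
    counts[zero] = 0.0
    return counts


def simulate_responses(config: CorpusConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a long-format trial table and its ground-truth sidecar.

    Sessions are parallel forms: each has its own word sample (predictors are
    z-scored pooled over both sessions).  The linear predictor is evaluated
    with the model module's :func:`linear_predictor`, guaranteeing that
    generation and fitting agree on the regression structure.
    """
    root = np.random.SeedSequence(config.seed)
    ss_words, ss_effects, ss_resp = root.spawn(3)
    n_u, n_v = config.words_per_session

    words = generate_predictors(
        n_u + n_v, config.predictor_correlation, seed=ss_words
    )
    # pooled z-scoring over both sessions' word samples
    session = np.array(["u"] * n_u + ["v"] * n_v)
    word_index = np.concatenate([np.arange(n_u), np.arange(n_v)])
    screen_id = word_index // config.screen_size

    effects = sample_random_effects(
        config.n_subjects, tuple(config.effect_specs) + tuple(config.spillover_specs),
        seed=ss_effects,
    )
    predictors = config.predictor_names
    spill_names = tuple(s.name for s in config.spillover_specs)

    # replicate the word table for every subject
    S = config.n_subjects
    n_words = n_u + n_v
    rep = pd.concat([words] * S, ignore_index=True)
    rep["subject"] = np.repeat(np.arange(S), n_words)
    rep["session"] = np.tile(session, S)
    rep["word_index"] = np.tile(word_index, S)
    rep["screen_id"] = np.tile(screen_id, S)
    rep["method"] = np.where(
        rep["session"] == "u", config.methods[0], config.methods[1]
    )

    # lagged z-scored predictors within screen (0 at screen starts: no
    # spillover contribution for the first word of a screen)
    X_lag = None
    if spill_names:
        lag_cols = {}
        for name in predictors:
            col = rep[f"{name}_z"].to_numpy().copy()
            lagged = np.roll(col, 1)
            first = np.tile(word_index % config.screen_size == 0, S)
            lagged[first] = 0.0
            lag_cols[name] = lagged
            rep[f"{name}_prev_z"] = lagged
        X_lag = np.column_stack([lag_cols[p] for p in predictors])

    # assemble a design bundle and evaluate the linear predictor through the
    # model module
    b_blocks = [effects["intercept"]]
    b_blocks += [effects[p] for p in predictors]
    if spill_names:
        # one lagged-slope block per predictor; predictors without a
        # spillover spec get a zero block
        zero = np.zeros((S, 2))
        b_blocks += [
            effects.get(f"{p}_prev", zero) for p in predictors
        ]
    b = np.stack(b_blocks)  # (B, S, 2)
    params = {
        "beta0": config.beta0,
        "beta_v": config.session_effect,
        "beta": np.array(
            [next(s.beta for s in config.effect_specs if s.name == p)
             for p in predictors]
        ),
        "b": b,
    }
    spill_betas = np.array([s.beta for s in config.spillover_specs])
    if spill_names and np.any(spill_betas != 0.0):
        params["beta_spill"] = spill_betas

    bundle = DesignMatrixBundle(
        subject_ids=np.arange(S),
        subject_idx=rep["subject"].to_numpy(),
        delta_v=(rep["session"] == "v").to_numpy(dtype=float),
        X=np.column_stack([rep[f"{p}_z"].to_numpy() for p in predictors]),
        X_lag=X_lag,
        y=np.zeros(len(rep)),
        predictors=predictors,
        session_labels=("u", "v"),
        n_rows_u=S * n_u,
        n_rows_v=S * n_v,
    )
    theta = linear_predictor(params, bundle)

    rng = np.random.default_rng(ss_resp)
    rep["response"] = _sample_family(theta, config, rng)

    id_cols = ["subject", "session", "method", "screen_id", "word_index",
               "response"]
    raw_cols = list(PREDICTORS)
    z_cols = [f"{p}_z" for p in PREDICTORS]
    prev_cols = [f"{p}_prev_z" for p in predictors] if spill_names else []
    trials = rep[id_cols + raw_cols + z_cols + prev_cols].reset_index(drop=True)

    truth = {
        "family": config.family,
        "beta0": config.beta0,
        "session_effect": config.session_effect,
        "sigma": config.sigma,
        "zip_zero_prob": config.zip_zero_prob,
        "effects": {
            s.name: {"beta": s.beta, "sd_u": s.sd_u, "sd_v": s.sd_v,
                     "rho": s.rho}
            for s in tuple(config.effect_specs) + tuple(config.spillover_specs)
        },
        "random_effects": {k: v.tolist() for k, v in effects.items()},
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "words_per_session": list(config.words_per_session),
    }
    return trials, truth


def write_corpus(config: CorpusConfig, out_dir) -> dict:
    """Write ``trials.csv`` and ``truth.json``; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials, truth = simulate_responses(config)
    trials_path = out / "trials.csv"
    truth_path = out / "truth.json"
    trials.to_csv(trials_path, index=False)
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"trials": str(trials_path), "truth": str(truth_path)}


def generate_scanpath(
    n_words: int,
    regression_prob: float = 0.15,
    skip_prob: float = 0.2,
    refix_prob: float = 0.15,
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FixationSequence, list[WordMeasures]]:
    """Stochastic left-to-right scanpath plus by-construction word measures.

    The reader sweeps the words left to right, skipping each with
    ``skip_prob``, refixating with ``refix_prob`` (geometric, capped), and
    launching a single-step regression to the previous word after a first
    pass with ``regression_prob``.  Because the generative process knows
    where every first pass starts and ends, the ground-truth measures are
    tracked during generation, giving an oracle that is independent of
    :func:`readrel.measures.compute_word_measures`.
    """
    for name, p in [("regression_prob", regression_prob),
                    ("skip_prob", skip_prob), ("refix_prob", refix_prob)]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    def draw_duration() -> float:
        return float(np.clip(np.round(rng.lognormal(5.3, 0.35)), 50, 1500))

    seq_words: list[int] = []
    seq_durs: list[float] = []
    n_fix = np.zeros(n_words, dtype=int)
    tft = np.zeros(n_words)
    ffd = np.full(n_words, np.nan)
    fprt = np.full(n_words, np.nan)
    rpd = np.full(n_words, np.nan)
    fpreg = np.full(n_words, np.nan)

    for w in range(n_words):
        if rng.random() < skip_prob:
            continue
        run = [draw_duration()]
        extra = 0
        while extra < 3 and rng.random() < refix_prob:
            run.append(draw_duration())
            extra += 1
        seq_words.extend([w] * len(run))
        seq_durs.extend(run)
        # in the sweep no word right of w has been fixated yet, so this run
        # is w's first pass
        ffd[w] = run[0]
        fprt[w] = sum(run)
        n_fix[w] += len(run)
        tft[w] += sum(run)
        regressed = w >= 1 and rng.random() < regression_prob
        if regressed:
            reg_dur = draw_duration()
            seq_words.append(w - 1)
            seq_durs.append(reg_dur)
            n_fix[w - 1] += 1
            tft[w - 1] += reg_dur
            fpreg[w] = 1.0
            # go-past window of w stays open until w+1 (or sequence end)
            rpd[w] = fprt[w] + reg_dur
        else:
            fpreg[w] = 0.0
            rpd[w] = fprt[w]

    sequence = FixationSequence(
        word_index=np.array(seq_words, dtype=int),
        duration=np.array(seq_durs, dtype=float),
    )
    truth = [
        WordMeasures(
            word_index=w,
            FFD=float(ffd[w]),
            FPRT=float(fprt[w]),
            RPD=float(rpd[w]),
            TFT=float(tft[w]),
            FPReg=float(fpreg[w]),
            SKIP=int(n_fix[w] == 0),
            N_FIX=int(n_fix[w]),
        )
        for w in range(n_words)
    ]
    return sequence, truth
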