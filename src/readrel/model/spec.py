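"""Model specification: likelihood family, predictors, priors, sampler settings.

The two-task model regresses a word-level reading measure on z-scored
psycholinguistic predictors, with by-subject-by-session random intercepts and
slopes.  For each predictor (and the intercept) the session-u and session-v
random effects of a subject are drawn from a bivariate normal whose
correlation is the reliability of that effect across sessions (or methods).

Priors are mildly informative and family-specific; random-effect standard
deviations get Exponential(2) priors and each 2x2 random-effect correlation
matrix gets an LKJ(2) prior.  A tighter preset (intercept centred at 5.5
log-ms with scale 0.1, slopes at scale 0.1) is available for hard-to-converge
continuous fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

FAMILIES = ("lognormal", "bernoulli", "zip")
VARIANTS = ("two-session", "cross-method")


@dataclass(frozen=True)
class NormalPrior:
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("prior scale must be > 0")


@dataclass(frozen=True)
class PriorSet:
    """Priors of the two-task model.

    ``beta`` is used for every population-level slope, including the session
    effect (whose prior the slope-scale class covers).  ``sd_rate`` and
    ``sigma_rate`` are Exponential rates; ``lkj_eta`` is the LKJ shape of the
    2x2 random-effect correlation blocks.  ``zip_logit`` is the prior of the
    intercept-only zero-inflation term on the logit scale.
    """

    beta0: NormalPrior
    beta: NormalPrior
    sd_rate: float = 2.0
    lkj_eta: float = 2.0
    sigma_rate: float = 2.0
    zip_logit: NormalPrior = NormalPrior(0.0, 1.0)

    def __post_init__(self) -> None:
        if self.sd_rate <= 0 or self.sigma_rate <= 0:
            raise ValueError("Exponential rates must be > 0")
        if self.lkj_eta <= 0:
            raise ValueError("LKJ shape must be > 0")

    @classmethod
    def default(cls, family: str) -> "PriorSet":
        if family == "lognormal":
            return cls(beta0=NormalPrior(6.0, 1.0), beta=NormalPrior(0.0, 1.0))
        if family in ("bernoulli", "zip"):
            # the intercept prior is unit-scale on the logit/log scale: a
            # tighter scale would fight the data and push the global level
            # into the zero-mean random intercepts
            return cls(beta0=NormalPrior(0.0, 1.0), beta=NormalPrior(0.0, 0.5))
        raise ValueError(f"unknown family {family!r}")

    @classmethod
    def tight(cls, family: str = "lognormal") -> "PriorSet":
        """High-precision preset used when a fit converges poorly."""
        base = cls.default(family)
        return replace(
            base, beta0=NormalPrior(5.5, 0.1), beta=NormalPrior(0.0, 0.1)
        )


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: family, predictors, variant and priors."""

    family: str
    predictors: tuple[str, ...]
    variant: str = "two-session"
    spillover: bool = False
    fixed_spillover: bool = False
    priors: PriorSet | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if len(self.predictors) < 1:
            raise ValueError("need at least one predictor")
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.priors is None:
            object.__setattr__(self, "priors", PriorSet.default(self.family))
        if self.fixed_spillover and not self.spillover:
            raise ValueError("fixed_spillover requires spillover")

    @property
    def block_names(self) -> tuple[str, ...]:
        """Random-effect blocks: intercept, each predictor, lagged predictors."""
        names = ("intercept",) + self.predictors
        if self.spillover:
            names = names + tuple(f"{p}_prev" for p in self.predictors)
        return names

    @property
    def n_blocks(self) -> int:
        return len(self.block_names)


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings: independent ensembles ("chains") of a fixed length.

    ``iterations`` counts ensemble moves per chain, of which ``warmup`` are
    discarded.  ``walkers=None`` picks an even number ~2.5x the parameter
    count.
    """

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    walkers: int | None = None
    thin: int = 1

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations < 2:
            raise ValueError("need >= 1 chain and >= 2 iterations")
        if not 0 <= self.warmup < self.iterations:
            raise ValueError("warmup must lie in [0, iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def escalated(self) -> "SamplerConfig":
        """Double the iterations (used together with :meth:`PriorSet.tight`)."""
        return replace(
            self, iterations=2 * self.iterations, warmup=2 * self.warmup
        )
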