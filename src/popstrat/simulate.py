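"""Generative model for admixed cohorts with structured genotypes and phenotypes.

Two source populations drift (and optionally "select") away from a shared
ancestral allele-frequency spectrum; individuals carry an admixture fraction
``a_i`` from Population 1, genotypes are Bernoulli draws from the
admixture-weighted population frequencies, and the phenotype mixes a
standardized genetic score, an ancestry-linked environmental exposure and
i.i.d. noise.  A Dirichlet sharing-matrix generator emulates the output of
haplotype-based ancestry profiling against a labeled reference panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SimulationParams",
    "TraitArchitecture",
    "FrequencyModel",
    "Cohort",
    "SharingMatrix",
    "draw_admixture",
    "draw_ancestral_freqs",
    "assign_architecture",
    "draw_population_freqs",
    "sample_genotypes",
    "build_phenotype",
    "make_cohort",
    "decouple_environment",
    "synth_sharing_matrix",
]

# substream labels hashed off the master seed so each stage can be re-run
# independently of the others
_STAGES = ("admixture", "ancestral", "architecture", "popfreqs", "genotypes", "noise")


class ParameterError(ValueError):
    """Raised when a simulation parameter is outside its valid range."""


@dataclass(frozen=True)
class SimulationParams:
    """All generative-model constants.

    Defaults are the model's published operating point: ``h=0.5``, ``e=0.5``,
    ``n_individuals=2000``, ``n_snps=4000``, ``l_eff=20``, ``a0=0.4``,
    ``beta0=1``, ``s=0.2``.  ``sigma_p2`` and ``causal_fraction`` are package
    defaults (the source model leaves them unstated).
    """

    n_individuals: int = 2000
    n_snps: int = 4000
    l_eff: float = 20.0
    a0: float = 0.4
    sigma_p2: float = 0.01
    s: float = 0.2
    beta0: float = 1.0
    h: float = 0.5
    e: float = 0.5
    causal_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ParameterError("n_individuals must be >= 1")
        if self.n_snps < 1:
            raise ParameterError("n_snps must be >= 1")
        if self.l_eff <= 0:
            raise ParameterError("l_eff must be > 0")
        if not (0.0 <= self.a0 <= 1.0):
            raise ParameterError(f"a0 must lie in [0, 1], got {self.a0}")
        if self.sigma_p2 < 0:
            raise ParameterError("sigma_p2 must be >= 0")
        if self.s < -1:
            raise ParameterError("s must be >= -1")
        if self.beta0 < 0:
            raise ParameterError("beta0 must be >= 0")
        if not (0.0 <= self.h <= 1.0):
            raise ParameterError("h must lie in [0, 1]")
        if not (0.0 <= self.e <= 1.0):
            raise ParameterError("e must lie in [0, 1]")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ParameterError("causal_fraction must lie in (0, 1]")

    @property
    def sigma_a2(self) -> float:
        """Admixture variance a0*(1-a0)/l_eff (binomial analogue)."""
        return self.a0 * (1.0 - self.a0) / self.l_eff

    @property
    def sigma_a(self) -> float:
        return float(np.sqrt(self.sigma_a2))

    def with_overrides(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        return cls(**d)

    def stage_rng(self, stage: str, salt: int = 0) -> np.random.Generator:
        """Independent generator for a named simulation stage."""
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}; one of {_STAGES}")
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STAGES.index(stage), salt])
        )


@dataclass
class TraitArchitecture:
    """Causal-SNP indicator ``c_l`` and nonnegative effect sizes ``beta_l``."""

    causal_indicator: np.ndarray
    effect_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.causal_indicator = np.asarray(self.causal_indicator, dtype=np.int8)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if self.causal_indicator.shape != self.effect_sizes.shape:
            raise ValueError("causal_indicator and effect_sizes must have equal length")
        if np.any(self.effect_sizes[self.causal_indicator == 0] != 0.0):
            raise ValueError("effect_sizes must be 0 for non-causal SNPs")

    @property
    def n_snps(self) -> int:
        return self.causal_indicator.size

    @property
    def causal_index(self) -> np.ndarray:
        return np.flatnonzero(self.causal_indicator)


@dataclass
class FrequencyModel:
    """Ancestral and per-population allele frequencies for each SNP."""

    ancestral: np.ndarray
    pop1: np.ndarray
    pop2: np.ndarray

    def __post_init__(self) -> None:
        self.ancestral = np.asarray(self.ancestral, dtype=float)
        self.pop1 = np.asarray(self.pop1, dtype=float)
        self.pop2 = np.asarray(self.pop2, dtype=float)
        if not (self.ancestral.shape == self.pop1.shape == self.pop2.shape):
            raise ValueError("frequency vectors must share a common length")
        if np.any((self.ancestral < 0.05 - 1e-12) | (self.ancestral > 0.5 + 1e-12)):
            raise ValueError("ancestral frequencies must lie in [0.05, 0.5]")
        for name, v in (("pop1", self.pop1), ("pop2", self.pop2)):
            if np.any((v < 0.0) | (v > 1.0)):
                raise ValueError(f"{name} frequencies must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return self.ancestral.size


@dataclass
class Cohort:
    """A simulated sample: ancestry, genotypes and phenotype components."""

    admixture: np.ndarray
    genotypes: np.ndarray
    genetic_component: np.ndarray
    environment: np.ndarray
    noise: np.ndarray
    phenotype: np.ndarray
    params: SimulationParams
    freqs: FrequencyModel
    arch: TraitArchitecture

    @property
    def n_individuals(self) -> int:
        return self.admixture.size

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class SharingMatrix:
    """Per-individual sharing totals with K labeled reference populations."""

    values: np.ndarray
    labels: Sequence[str]
    group: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("labels must match the number of columns")
        if self.values.shape[1] < 2:
            raise ValueError("need K >= 2 reference populations")
        if np.any(self.values < 0):
            raise ValueError("sharing values must be nonnegative")
        if np.any(self.values.sum(axis=1) <= 0):
            raise ValueError("every row must have a positive total")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_populations(self) -> int:
        return self.values.shape[1]


def _clamped_normal(
    mean: np.ndarray | float,
    var: np.ndarray | float,
    size,
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = 1.0,
) -> np.ndarray:
    """Normal draws clamped to [lo, hi].

    Clamping (not rejection) is deliberate: it lets mass sit exactly at the
    boundary, so admixture proportions and allele frequencies of exactly 0
    or 1 can occur.
    """
    sd = np.sqrt(np.asarray(var, dtype=float))
    draws = np.asarray(mean, dtype=float) + sd * rng.standard_normal(size)
    return np.clip(draws, lo, hi)


def draw_admixture(
    params: SimulationParams,
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw admixture fractions a_i ~ Normal(a0, a0(1-a0)/l_eff) clamped to [0, 1]."""
    n = params.n_individuals if n is None else int(n)
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = params.stage_rng("admixture") if rng is None else rng
    return _clamped_normal(params.a0, params.sigma_a2, n, rng)


def draw_ancestral_freqs(
    params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Ancestral allele frequencies p_l ~ Uniform(0.05, 0.5), length n_snps."""
    rng = params.stage_rng("ancestral") if rng is None else rng
    return rng.uniform(0.05, 0.5, size=params.n_snps)


def assign_architecture(
    params: SimulationParams,
    ancestral: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> TraitArchitecture:
    """Pick causal SNPs and draw effect sizes beta_l ~ Uniform(0, beta0*p(1-p))."""
    ancestral = np.asarray(ancestral, dtype=float)
    L = ancestral.size
    n_causal = int(round(params.causal_fraction * L))
    if n_causal < 1:
        raise ParameterError(
            "causal_fraction * n_snps rounds to zero causal SNPs; "
            "require n_snps * causal_fraction >= 1"
        )
    rng = params.stage_rng("architecture") if rng is None else rng
    causal = np.zeros(L, dtype=np.int8)
    causal[rng.choice(L, size=n_causal, replace=False)] = 1
    upper = params.beta0 * ancestral * (1.0 - ancestral)
    beta = np.where(causal == 1, rng.uniform(0.0, 1.0, size=L) * upper, 0.0)
    return TraitArchitecture(causal_indicator=causal, effect_sizes=beta)


def draw_population_freqs(
    ancestral: np.ndarray,
    arch: TraitArchitecture,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> FrequencyModel:
    """Drifted per-population frequencies.

    Population 1 has its causal SNPs shifted upward by the selection factor
    ``(1 + c_l * s)``; Population 2 drifts around the ancestral frequency.
    Both are Normal(mean, p(1-p)*sigma_p2) clamped to [0, 1].
    """
    if params.sigma_p2 < 0:
        raise ParameterError("sigma_p2 must be >= 0")
    ancestral = np.asarray(ancestral, dtype=float)
    rng = params.stage_rng("popfreqs") if rng is None else rng
    var = ancestral * (1.0 - ancestral) * params.sigma_p2
    mean1 = ancestral * (1.0 + arch.causal_indicator * params.s)
    pop1 = _clamped_normal(mean1, var, ancestral.size, rng)
    pop2 = _clamped_normal(ancestral, var, ancestral.size, rng)
    return FrequencyModel(ancestral=ancestral, pop1=pop1, pop2=pop2)


def sample_genotypes(
    admixture: np.ndarray,
    freqs: FrequencyModel,
    rng: Optional[np.random.Generator] = None,
    ploidy: int = 1,
) -> np.ndarray:
    """Bernoulli genotypes X_il ~ bern(a_i*p_l1 + (1-a_i)*p_l2).

    ``ploidy=2`` gives Binomial(2, .) dosages instead; the model as published
    uses single draws, so that is the default.
    """
    a = np.asarray(admixture, dtype=float)[:, None]
    prob = a * freqs.pop1[None, :] + (1.0 - a) * freqs.pop2[None, :]
    assert np.all((prob >= -1e-12) & (prob <= 1 + 1e-12)), "cell probability out of [0,1]"
    prob = np.clip(prob, 0.0, 1.0)
    rng = np.random.default_rng() if rng is None else rng
    if ploidy == 1:
        return (rng.random(prob.shape) < prob).astype(np.int8)
    if ploidy == 2:
        return rng.binomial(2, prob).astype(np.int8)
    raise ParameterError("ploidy must be 1 or 2")


def _standardize(v: np.ndarray) -> np.ndarray:
    """Center to mean 0, scale to unit sample variance (ddof=1)."""
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(
            "genetic component has zero variance: no causal SNP segregates; "
            "increase n_individuals, causal_fraction or allele frequencies"
        )
    return (v - v.mean()) / sd


def build_phenotype(
    X: np.ndarray,
    arch: TraitArchitecture,
    admixture: np.ndarray,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (genetic_component, environment, noise, phenotype).

    Y^G = X @ beta standardized to sample mean 0 / variance 1;
    E = (a - a0)/sigma_a;  eps ~ Normal(0, 1);
    Y = h*Y^G + (1-h)*e*E + (1-h)*(1-e)*eps.
    """
    if params.e > 0 and params.sigma_a == 0:
        raise ParameterError("sigma_a = 0 with e > 0: environment is undefined")
    yg = _standardize(np.asarray(X, dtype=float) @ arch.effect_sizes)
    a = np.asarray(admixture, dtype=float)
    env = (a - params.a0) / params.sigma_a if params.sigma_a > 0 else np.zeros_like(a)
    rng = params.stage_rng("noise") if rng is None else rng
    eps = rng.standard_normal(a.size)
    y = combine_phenotype(yg, env, eps, params)
    return yg, env, eps, y


def combine_phenotype(
    yg: np.ndarray, env: np.ndarray, eps: np.ndarray, params: SimulationParams
) -> np.ndarray:
    """The phenotype mixing formula, exposed so cohorts can be rebuilt."""
    h, e = params.h, params.e
    return h * yg + (1.0 - h) * e * env + (1.0 - h) * (1.0 - e) * eps


def make_cohort(
    params: SimulationParams,
    freqs: Optional[FrequencyModel] = None,
    arch: Optional[TraitArchitecture] = None,
    salt: int = 0,
) -> Cohort:
    """Simulate a complete cohort.

    Passing ``freqs``/``arch`` from a previous (training) run reuses that
    generative model while drawing new individuals — the test-set recipe.
    ``salt`` perturbs the per-individual substreams only, so train/test
    cohorts built from the same params differ in individuals, not model.
    """
    if (freqs is None) != (arch is None):
        raise ValueError("supply freqs and arch together, or neither")
    if freqs is None:
        ancestral = draw_ancestral_freqs(params)
        arch = assign_architecture(params, ancestral)
        freqs = draw_population_freqs(ancestral, arch, params)
    else:
        if freqs.n_snps != params.n_snps or arch.n_snps != params.n_snps:
            raise ValueError(
                f"supplied freqs/arch have {freqs.n_snps}/{arch.n_snps} SNPs "
                f"but params.n_snps = {params.n_snps}"
            )
    a = draw_admixture(params, params.n_individuals, params.stage_rng("admixture", salt))
    X = sample_genotypes(a, freqs, params.stage_rng("genotypes", salt))
    yg, env, eps, y = build_phenotype(X, arch, a, params, params.stage_rng("noise", salt))
    return Cohort(
        admixture=a,
        genotypes=X,
        genetic_component=yg,
        environment=env,
        noise=eps,
        phenotype=y,
        params=params,
        freqs=freqs,
        arch=arch,
    )


def decouple_environment(
    cohort: Cohort,
    mode: str = "permute",
    rng: Optional[np.random.Generator] = None,
) -> Cohort:
    """Break the ancestry-environment link and rebuild the phenotype.

    ``permute`` shuffles E across individuals (marginal distribution kept);
    ``zero`` removes the environmental component entirely.  Genotypes, the
    genetic component and the noise vector are untouched.
    """
    params = cohort.params
    if params.e == 0:
        warnings.warn("cohort built with e=0: decoupling is a no-op", stacklevel=2)
        return cohort
    if mode == "permute":
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 97])) if rng is None else rng
        env = rng.permutation(cohort.environment)
    elif mode == "zero":
        env = np.zeros_like(cohort.environment)
    else:
        raise ValueError("mode must be 'permute' or 'zero'")
    y = combine_phenotype(cohort.genetic_component, env, cohort.noise, params)
    return Cohort(
        admixture=cohort.admixture,
        genotypes=cohort.genotypes,
        genetic_component=cohort.genetic_component,
        environment=env,
        noise=cohort.noise,
        phenotype=y,
        params=params,
        freqs=cohort.freqs,
        arch=cohort.arch,
    )


def synth_sharing_matrix(
    n: int,
    n_populations: int,
    concentration: float = 50.0,
    group_means: Optional[np.ndarray] = None,
    row_total: float = 100.0,
    seed: int = 0,
) -> SharingMatrix:
    """Synthetic individuals-by-reference-populations sharing matrix.

    Each individual belongs to one of K groups; its sharing row is a
    Dirichlet draw centered on the group's mean profile, scaled to
    ``row_total``.  ``concentration`` tunes within-group spread
    (``np.inf`` collapses every row onto its group mean).  Default group
    means put weight 0.5 on the own population and spread the rest evenly,
    giving clearly separated groups.
    """
    if n_populations < 2:
        raise ParameterError("need n_populations >= 2")
    if not concentration > 0:
        raise ParameterError("concentration must be > 0")
    K = n_populations
    if group_means is None:
        group_means = np.full((K, K), 0.5 / (K - 1))
        np.fill_diagonal(group_means, 0.5)
    else:
        group_means = np.asarray(group_means, dtype=float)
        if group_means.shape != (K, K):
            raise ValueError("group_means must be K x K")
        if np.any(group_means < 0) or np.any(group_means.sum(axis=1) <= 0):
            raise ValueError("group_means rows must be nonnegative with positive sums")
        group_means = group_means / group_means.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    group = rng.integers(0, K, size=n)
    if np.isinf(concentration):
        rows = group_means[group]
    else:
        alpha = np.maximum(concentration * group_means[group], 1e-12)
        rows = rng.gamma(shape=alpha)
        rows = rows / rows.sum(axis=1, keepdims=True)
    labels = [f"pop{k + 1}" for k in range(K)]
    return SharingMatrix(values=row_total * rows, labels=labels, group=group)
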