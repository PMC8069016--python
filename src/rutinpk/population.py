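"""Population (mixed-effects) layer on top of the structural models.

An individual structural parameter ``P_i`` is obtained from the population
value ``P_pop`` on a transformed scale::

    h(P_i) = h(P_pop) + beta_{covariate level} + eta_i

where ``h`` is ``log`` for positive parameters or ``logit`` for parameters
constrained to (0, 1) on their unit scale (the central volume V in the IV
model, the first-site fraction F1 in the oral model), ``beta`` is an
additive covariate shift (reference level carries beta = 0), and
``eta_i ~ N(0, Sigma)`` is the subject's random effect.  ``Sigma`` is built
from per-parameter standard deviations (Omega) and an optional correlation
structure; parameters without a random effect simply have no eta component.

Residual error is "combined": an observation y around a prediction f has
standard deviation ``a + b*f`` (ng/mL) by default; the alternative
``sqrt(a^2 + (b*f)^2)`` form is available via ``form="quadratic"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .structural import IVParameters, OralParameters

__all__ = [
    "LOG",
    "LOGIT",
    "transform_value",
    "inverse_transform",
    "CovariateEffect",
    "RandomEffectsSpec",
    "ResidualErrorModel",
    "PopulationModel",
    "individual_parameters",
    "sample_etas",
    "residual_sd",
    "IV_PARAM_NAMES",
    "ORAL_PARAM_NAMES",
]

LOG = "log"
LOGIT = "logit"

IV_PARAM_NAMES = ("V", "k", "k12", "k21")
ORAL_PARAM_NAMES = ("ka1", "ka2", "F1", "Tlag2", "V", "k", "k12", "k21")

#: default transform per parameter and structural model
DEFAULT_TRANSFORMS = {
    "iv": {"V": LOGIT, "k": LOG, "k12": LOG, "k21": LOG},
    "oral": {"ka1": LOG, "ka2": LOG, "F1": LOGIT, "Tlag2": LOG,
             "V": LOG, "k": LOG, "k12": LOG, "k21": LOG},
}


class ModelSpecError(ValueError):
    """Raised for inconsistent population-model specifications."""


def transform_value(p, kind: str):
    """Map a unit-scale parameter to its unconstrained scale."""
    p = np.asarray(p, dtype=float)
    if kind == LOG:
        if np.any(p <= 0):
            raise ModelSpecError("log transform requires a positive value")
        return np.log(p)
    if kind == LOGIT:
        if np.any((p <= 0) | (p >= 1)):
            raise ModelSpecError(
                "logit transform requires a value in (0, 1) on the unit scale"
            )
        return np.log(p / (1.0 - p))
    raise ModelSpecError(f"unknown transform {kind!r}")


def inverse_transform(x, kind: str):
    """Back-transform from the unconstrained scale to the unit scale."""
    x = np.asarray(x, dtype=float)
    if kind == LOG:
        return np.exp(x)
    if kind == LOGIT:
        return 1.0 / (1.0 + np.exp(-x))
    raise ModelSpecError(f"unknown transform {kind!r}")


def transform_jacobian(p, kind: str):
    """d(unit scale)/d(transformed scale) evaluated at unit-scale value p."""
    p = np.asarray(p, dtype=float)
    if kind == LOG:
        return p
    if kind == LOGIT:
        return p * (1.0 - p)
    raise ModelSpecError(f"unknown transform {kind!r}")


@dataclass(frozen=True)
class CovariateEffect:
    """Additive shift ``beta`` on the transformed scale of ``parameter``
    for subjects at covariate ``level`` (reference level has no effect)."""

    parameter: str
    level: str
    beta: float


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Inter-individual variability: SD per parameter (transformed scale)
    plus optional pairwise correlations."""

    sd: Mapping[str, float]
    corr: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in self.sd.items():
            if not np.isfinite(s) or s < 0:
                raise ModelSpecError(f"Omega SD for {name!r} must be >= 0, got {s!r}")
        names = self.names
        for (p1, p2), r in self.corr.items():
            if p1 not in names or p2 not in names:
                raise ModelSpecError(
                    f"correlation ({p1}, {p2}) references a parameter without a random effect"
                )
            if not -1.0 < r < 1.0:
                raise ModelSpecError(f"correlation must be in (-1, 1), got {r!r}")
        if self.sd:
            eig = np.linalg.eigvalsh(self.correlation_matrix())
            if np.min(eig) < -1e-10:
                raise ModelSpecError("correlation matrix is not positive semi-definite")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sd.keys())

    def correlation_matrix(self) -> np.ndarray:
        names = self.names
        q = len(names)
        R = np.eye(q)
        idx = {n: i for i, n in enumerate(names)}
        for (p1, p2), r in self.corr.items():
            R[idx[p1], idx[p2]] = R[idx[p2], idx[p1]] = r
        return R

    def covariance(self) -> np.ndarray:
        s = np.array([self.sd[n] for n in self.names], dtype=float)
        return self.correlation_matrix() * np.outer(s, s)


@dataclass(frozen=True)
class ResidualErrorModel:
    """Combined residual error: observation y = f + sd(f) * eps, eps~N(0,1).

    ``form="linear"`` (default): sd(f) = a + b*f.
    ``form="quadratic"``: sd(f) = sqrt(a^2 + (b*f)^2).
    """

    a: float
    b: float
    form: str = "linear"

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ModelSpecError("residual components a, b must be >= 0")
        if self.form not in ("linear", "quadratic"):
            raise ModelSpecError(f"unknown residual form {self.form!r}")

    def sd(self, f):
        f = np.asarray(f, dtype=float)
        if np.any(f < 0):
            raise ModelSpecError("predicted concentration must be >= 0")
        if self.form == "linear":
            return self.a + self.b * f
        return np.sqrt(self.a ** 2 + (self.b * f) ** 2)


@dataclass(frozen=True)
class PopulationModel:
    """Complete population specification for one structural model.

    Parameters
    ----------
    structural : {"iv", "oral"}
    fixed_effects : unit-scale population values per structural parameter.
    covariate_axis : name of the single categorical covariate axis
        ("source" for IV: RU/GEXT; "dose_group" for oral).
    levels : declared covariate levels; the first is the reference.
    effects : covariate effects (betas); reference level must not appear.
    random_effects : Omega SDs and correlations.
    error : residual error model.
    """

    structural: str
    fixed_effects: Mapping[str, float]
    covariate_axis: str
    levels: tuple[str, ...]
    effects: tuple[CovariateEffect, ...]
    random_effects: RandomEffectsSpec
    error: ResidualErrorModel

    def __post_init__(self) -> None:
        if self.structural not in ("iv", "oral"):
            raise ModelSpecError(f"structural must be 'iv' or 'oral', got {self.structural!r}")
        names = self.param_names
        missing = [n for n in names if n not in self.fixed_effects]
        if missing:
            raise ModelSpecError(f"missing fixed effects for {missing}")
        if len(self.levels) < 1:
            raise ModelSpecError("at least a reference covariate level is required")
        ref = self.levels[0]
        for eff in self.effects:
            if eff.parameter not in names:
                raise ModelSpecError(f"covariate effect on unknown parameter {eff.parameter!r}")
            if eff.level == ref:
                raise ModelSpecError("the reference level must not carry a beta")
            if eff.level not in self.levels:
                raise ModelSpecError(
                    f"covariate effect for undeclared level {eff.level!r}; "
                    f"declared levels: {list(self.levels)}"
                )
        for n in self.random_effects.names:
            if n not in names:
                raise ModelSpecError(f"random effect on unknown parameter {n!r}")
        # validates transform constraints (e.g. logit requires value in (0,1))
        self.phi_population()

    # -- structure ---------------------------------------------------------

    @property
    def param_names(self) -> tuple[str, ...]:
        return IV_PARAM_NAMES if self.structural == "iv" else ORAL_PARAM_NAMES

    def transform_of(self, name: str) -> str:
        return DEFAULT_TRANSFORMS[self.structural][name]

    @property
    def iiv_names(self) -> tuple[str, ...]:
        """Parameters carrying a random effect, in canonical order."""
        re_names = set(self.random_effects.names)
        return tuple(n for n in self.param_names if n in re_names)

    def beta_for(self, parameter: str, level: str) -> float:
        for eff in self.effects:
            if eff.parameter == parameter and eff.level == level:
                return eff.beta
        return 0.0

    # -- evaluation --------------------------------------------------------

    def phi_population(self, level: str | None = None) -> np.ndarray:
        """Transformed-scale parameter vector at a covariate level
        (population values + betas; no random effect)."""
        if level is None:
            level = self.levels[0]
        if level not in self.levels:
            raise ModelSpecError(
                f"unknown covariate level {level!r}; declared levels: {list(self.levels)}"
            )
        phi = np.array([
            transform_value(self.fixed_effects[n], self.transform_of(n))
            + self.beta_for(n, level)
            for n in self.param_names
        ])
        return phi

    def individual_parameters(self, level: str, eta=None):
        """Individual structural parameters for a covariate level and a
        random-effect vector (ordered as :attr:`iiv_names`)."""
        phi = self.phi_population(level)
        iiv = self.iiv_names
        if eta is None:
            eta = np.zeros(len(iiv))
        eta = np.asarray(eta, dtype=float)
        if isinstance(eta, np.ndarray) and eta.shape != (len(iiv),):
            raise ModelSpecError(
                f"eta must have length {len(iiv)} (parameters {iiv}), got shape {eta.shape}"
            )
        names = self.param_names
        pos = {n: i for i, n in enumerate(names)}
        for e, n in zip(eta, iiv):
            phi[pos[n]] += e
        unit = {n: float(inverse_transform(phi[pos[n]], self.transform_of(n)))
                for n in names}
        cls = IVParameters if self.structural == "iv" else OralParameters
        return cls(**unit)

    def sample_etas(self, n: int, seed=None) -> np.ndarray:
        """Draw ``n`` random-effect vectors (zero-mean MVN with the Omega
        covariance), ordered as :attr:`iiv_names`.  Reproducible under a
        fixed seed (an int or a numpy Generator)."""
        if n < 1:
            raise ModelSpecError("n must be >= 1")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        iiv = self.iiv_names
        q = len(iiv)
        if q == 0:
            return np.zeros((n, 0))
        cov_full = self.random_effects.covariance()
        order = [self.random_effects.names.index(nme) for nme in iiv]
        cov = cov_full[np.ix_(order, order)]
        return rng.multivariate_normal(np.zeros(q), cov, size=n, method="cholesky"
                                       if np.all(np.linalg.eigvalsh(cov) > 0) else "svd")


# -- spec-level convenience wrappers ---------------------------------------


def individual_parameters(pop: PopulationModel, covariates: str, eta=None):
    """Map population values + covariate level + random effects to an
    individual parameter set (see :meth:`PopulationModel.individual_parameters`)."""
    return pop.individual_parameters(covariates, eta)


def sample_etas(pop: PopulationModel, n: int, seed=None) -> np.ndarray:
    return pop.sample_etas(n, seed)


def residual_sd(err: ResidualErrorModel, f):
    """Residual standard deviation (ng/mL) at predicted concentration f."""
    return err.sd(f)
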