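"""Structural model for aggregate placebo response in Alzheimer's disease trials.

The observed quantity is the mean change from baseline in the 11-item
ADAS-cog score of a placebo arm (points; positive = cognitive worsening).
It is decomposed into a linear disease-progression term and a transient
placebo effect:

    S(t) = alpha * t + Pbo(t)

``alpha`` is the disease-progression rate in points/week (annualised as
``alpha * 52``).  The default placebo-effect form is an Emax function of
time,

    Pbo(t) = beta * t / (ET50 + t)

with asymptote ``beta`` (points; negative = transient improvement) and
half-time ``ET50`` (weeks).  Sigmoid-Emax, exponential-onset and inverse
Bateman alternatives are provided for structural-model comparison.

Study-level heterogeneity acts proportionally on alpha and beta,
``P_i = P_pop * (1 + eta_i)``, which allows individual study slopes and
placebo extents to change sign (worsening placebo response / nocebo).
Covariates scale the typical values multiplicatively; every covariate
function equals exactly 1 at its reference value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ADAS_SCALE_MAX",
    "CovariateEffect",
    "PopulationParameters",
    "placebo_time_profile",
    "placebo_effect",
    "structural_response",
    "covariate_multiplier",
    "combined_multiplier",
    "individual_parameters",
    "residual_sd",
]

#: Ceiling of the 11-item ADAS-cog scale (points).
ADAS_SCALE_MAX = 70.0

PLACEBO_FORMS = ("emax", "sigmoid_emax", "exponential", "inverse_bateman")
COVARIATE_FORMS = ("power", "linear", "inverse_u", "indicator")


class CovariateDomainError(ValueError):
    """A covariate value lies outside the domain of its functional form."""


@dataclass(frozen=True)
class CovariateEffect:
    """A multiplicative covariate function attached to a fixed effect.

    Parameters
    ----------
    covariate:
        Name of the study-level covariate (e.g. ``"baseline_adas"``).
    parameter:
        Which fixed effect the factor multiplies, ``"alpha"`` or ``"beta"``.
    form:
        ``"power"``, ``"linear"``, ``"inverse_u"`` or ``"indicator"``.
    theta:
        Shape coefficient (exponent for power/inverse-U, slope otherwise).
    ref:
        Reference covariate value at which the factor equals 1.
    scale_max:
        Scale ceiling used by the inverse-U form (ADAS-cog: 70).
    """

    covariate: str
    parameter: str = "alpha"
    form: str = "power"
    theta: float = 0.0
    ref: float = 1.0
    scale_max: float = ADAS_SCALE_MAX

    def __post_init__(self) -> None:
        if self.parameter not in ("alpha", "beta"):
            raise ValueError(f"unknown target parameter {self.parameter!r}")
        if self.form not in COVARIATE_FORMS:
            raise ValueError(f"unknown covariate form {self.form!r}")

    @property
    def key(self) -> str:
        return f"{self.covariate}:{self.parameter}:{self.form}"

    def factor(self, value):
        return covariate_multiplier(
            value, self.ref, self.theta, self.form, self.scale_max,
            name=self.covariate,
        )


@dataclass
class PopulationParameters:
    """Population (typical) parameters plus variance components.

    ``omega_alpha``/``omega_beta`` are standard deviations of the
    proportional study-level random effects on alpha and beta; ``rho`` is
    their correlation.  ``delta`` is the additive residual SD in points on
    the per-subject scale, weighted by 1/sqrt(N) at the arm level.
    """

    alpha_typ: float = 0.1
    beta_typ: float = -1.5
    et50: float = 8.0
    hill: float = 1.0
    k_onset: float = 0.2
    k_offset: float = 0.05
    omega_alpha: float = 0.0
    omega_beta: float = 0.0
    rho: float = 0.0
    delta: float = 5.0
    placebo_form: str = "emax"
    covariate_effects: tuple[CovariateEffect, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.covariate_effects = tuple(self.covariate_effects)
        self.validate()

    def validate(self) -> None:
        if self.placebo_form not in PLACEBO_FORMS:
            raise ValueError(f"unknown placebo form {self.placebo_form!r}")
        if self.placebo_form in ("emax", "sigmoid_emax") and not self.et50 > 0:
            raise ValueError("et50 must be > 0")
        if self.placebo_form == "sigmoid_emax" and not self.hill > 0:
            raise ValueError("hill must be > 0")
        if self.delta < 0:
            # zero is permitted for noise-free simulation; estimation
            # requires a positive residual SD
            raise ValueError("delta must be >= 0")
        if self.omega_alpha < 0 or self.omega_beta < 0:
            raise ValueError("omega must be >= 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")

    def effects_on(self, parameter: str) -> tuple[CovariateEffect, ...]:
        return tuple(e for e in self.covariate_effects if e.parameter == parameter)

    def omega_matrix(self) -> np.ndarray:
        """2x2 covariance of (eta_alpha, eta_beta)."""
        oa, ob, r = self.omega_alpha, self.omega_beta, self.rho
        return np.array([[oa**2, r * oa * ob], [r * oa * ob, ob**2]])

    def replace(self, **kw) -> "PopulationParameters":
        return replace(self, **kw)


def placebo_time_profile(t, p: PopulationParameters):
    """Unit placebo time profile g(t) with Pbo(t) = beta * g(t); g(0) = 0.

    For the Emax and sigmoid-Emax forms g rises monotonically to 1; for
    the exponential-onset form g = 1 - exp(-k_onset t); for the inverse
    Bateman form g rises to a peak of exactly 1 and washes out, keeping
    beta the extremum of the curve.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    form = p.placebo_form
    if form == "emax":
        return t / (p.et50 + t)
    if form == "sigmoid_emax":
        th = np.power(t, p.hill)
        return th / (p.et50**p.hill + th)
    if form == "exponential":
        return 1.0 - np.exp(-p.k_onset * t)
    if form == "inverse_bateman":
        kon, koff = p.k_onset, p.k_offset
        if not (kon > koff > 0):
            raise ValueError("inverse_bateman requires k_onset > k_offset > 0")
        tpeak = np.log(kon / koff) / (kon - koff)
        norm = np.exp(-koff * tpeak) - np.exp(-kon * tpeak)
        return (np.exp(-koff * t) - np.exp(-kon * t)) / norm
    raise ValueError(f"unknown placebo form {form!r}")


def placebo_effect(t, p: PopulationParameters, beta: float | None = None):
    """Placebo effect Pbo(t) in points; ``beta`` overrides the typical value."""
    b = p.beta_typ if beta is None else beta
    return b * placebo_time_profile(t, p)


def structural_response(t, alpha_i: float, beta_i: float, p: PopulationParameters):
    """Mean change from baseline S(t) = alpha_i*t + beta_i*g(t), points."""
    t = np.asarray(t, dtype=float)
    return alpha_i * t + placebo_effect(t, p, beta=beta_i)


def covariate_multiplier(value, ref, theta, form="power",
                         scale_max=ADAS_SCALE_MAX, name="covariate"):
    """Multiplicative covariate factor; exactly 1 at ``value == ref``.

    power:     (value/ref)**theta
    linear:    1 + theta*(value/ref - 1)
    inverse_u: ((value/ref) * (scale_max - value)/(scale_max - ref))**theta
    indicator: 1 + theta*(value - ref)   (for 0/1 dichotomous covariates)

    The inverse-U form captures the boundedness of the ADAS-cog scale:
    its unnormalised kernel value*(scale_max - value) peaks at
    scale_max/2, so progression is fastest for mid-scale severity.
    """
    value = np.asarray(value, dtype=float)
    if form == "power":
        if np.any(value <= 0) or ref <= 0:
            raise CovariateDomainError(
                f"{name}: power form requires positive value and reference")
        return (value / ref) ** theta
    if form == "linear":
        if ref == 0:
            raise CovariateDomainError(f"{name}: linear form requires ref != 0")
        return 1.0 + theta * (value / ref - 1.0)
    if form == "inverse_u":
        if np.any(value <= 0) or np.any(value >= scale_max) or not (0 < ref < scale_max):
            raise CovariateDomainError(
                f"{name}: inverse-U form requires 0 < value < {scale_max} "
                f"and 0 < ref < {scale_max}")
        kernel = (value / ref) * (scale_max - value) / (scale_max - ref)
        return kernel ** theta
    if form == "indicator":
        return 1.0 + theta * (value - ref)
    raise ValueError(f"unknown covariate form {form!r}")


def combined_multiplier(p: PopulationParameters, parameter: str,
                        covariates: Mapping[str, float]):
    """Product of all covariate factors acting on ``parameter``."""
    f = 1.0
    for eff in p.effects_on(parameter):
        if eff.covariate not in covariates:
            raise KeyError(f"missing covariate {eff.covariate!r}")
        f = f * eff.factor(covariates[eff.covariate])
    return f


def individual_parameters(p: PopulationParameters, eta, covariates: Mapping[str, float]):
    """Study-level (alpha_i, beta_i) from random effects and covariates.

    alpha_i = alpha_typ * prod(factors) * (1 + eta_alpha), and likewise
    for beta: the proportional random-effect model, which permits
    negative study slopes and positive (nocebo) placebo extents.
    """
    eta_a, eta_b = eta
    alpha_i = p.alpha_typ * combined_multiplier(p, "alpha", covariates) * (1.0 + eta_a)
    beta_i = p.beta_typ * combined_multiplier(p, "beta", covariates) * (1.0 + eta_b)
    return alpha_i, beta_i


def residual_sd(delta: float, n) -> float:
    """Residual SD of an arm-level mean: delta / sqrt(n)."""
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    if not delta > 0:
        raise ValueError("delta must be > 0")
    return delta / np.sqrt(n)
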