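"""Marginal-likelihood estimation for the aggregate disease-progression model.

Each study contributes a small vector of arm-mean observations whose
expectation is ``alpha_i * t + beta_i * g(t)`` with proportional
study-level random effects on (alpha, beta).  Because the nonlinear
parameters (ET50 and friends) carry no inter-study variability, the
model is *linear* in the random effects, so the Laplace approximation to
the marginal likelihood — an expansion about the conditional mode of
eta — is exact for these forms.  The inner mode problem is quadratic and
is solved by a single Newton step (a 2x2 linear solve per study).

Three routes to the same integral are provided:

- ``laplace``: mode + curvature factorisation (the default; also the
  FOCE-type objective, since with a purely additive residual the
  "interaction" term vanishes and the conditional expansion coincides
  with Laplace);
- ``foce``: the marginalised Gaussian form Sigma = X Omega X' + D,
  evaluated by batched Cholesky — an algebraically independent
  computational path used for cross-checking;
- ``agq``: adaptive Gauss-Hermite quadrature centred at the conditional
  mode, the slow reference oracle for testing the approximations.

The OFV convention is the full -2 log marginal likelihood including
2*pi constants; only OFV differences are ever interpreted (LRT, AIC).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .data import TrialSet
from .model import (
    CovariateEffect,
    PopulationParameters,
    covariate_multiplier,
    placebo_time_profile,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "neg2ll",
    "fit",
    "empirical_bayes",
    "select_structural",
    "final_model_spec",
    "base_model_spec",
]

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e10


@dataclass(frozen=True)
class ModelSpec:
    """Which structural form, covariate effects and variance components
    are estimated.  Variance components not estimated are fixed at the
    ``*_fixed`` values (0 by default, mirroring the convention of fixing
    a heavily shrunk random effect to zero)."""

    placebo_form: str = "emax"
    covariate_effects: tuple[CovariateEffect, ...] = ()
    estimate_omega_alpha: bool = True
    estimate_omega_beta: bool = True
    estimate_rho: bool = True
    omega_alpha_fixed: float = 0.0
    omega_beta_fixed: float = 0.0
    rho_fixed: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))

    @property
    def transformed_names(self) -> tuple[str, ...]:
        names = ["alpha", "beta"]
        if self.placebo_form in ("emax", "sigmoid_emax"):
            names.append("log_et50")
        if self.placebo_form == "sigmoid_emax":
            names.append("log_hill")
        if self.placebo_form == "exponential":
            names.append("log_k_onset")
        if self.placebo_form == "inverse_bateman":
            names += ["log_k_offset", "log_dk"]
        for eff in self.covariate_effects:
            names.append(f"theta[{eff.covariate}->{eff.parameter}:{eff.form}]")
        if self.estimate_omega_alpha:
            names.append("log_omega_alpha")
        if self.estimate_omega_beta:
            names.append("log_omega_beta")
        if self.estimate_omega_alpha and self.estimate_omega_beta and self.estimate_rho:
            names.append("atanh_rho")
        names.append("log_delta")
        return tuple(names)

    @property
    def n_parameters(self) -> int:
        return len(self.transformed_names)

    def with_effect(self, eff: CovariateEffect) -> "ModelSpec":
        return replace(self, covariate_effects=self.covariate_effects + (eff,))

    def without_effect(self, key: str) -> "ModelSpec":
        kept = tuple(e for e in self.covariate_effects if e.key != key)
        return replace(self, covariate_effects=kept)


def base_model_spec(placebo_form: str = "emax") -> ModelSpec:
    """Covariate-free structural model with full (alpha, beta) IIV."""
    return ModelSpec(placebo_form=placebo_form)


def final_model_spec(ts: TrialSet | None = None) -> ModelSpec:
    """The selected covariate model: inverse-U baseline-ADAS and power
    age effects on the progression rate."""
    ref_adas = ts.reference("baseline_adas") if ts is not None else 24.5
    ref_age = ts.reference("baseline_age") if ts is not None else 73.5
    return ModelSpec(covariate_effects=(
        CovariateEffect("baseline_adas", "alpha", "inverse_u", 0.0, ref=ref_adas),
        CovariateEffect("baseline_age", "alpha", "power", 0.0, ref=ref_age),
    ))


# ---------------------------------------------------------------------------
# parameter transforms

def pack(p: PopulationParameters, spec: ModelSpec) -> np.ndarray:
    """Natural parameters -> unconstrained vector (log / atanh transforms)."""
    theta_map = {e.key: e.theta for e in p.covariate_effects}
    x = [p.alpha_typ, p.beta_typ]
    if spec.placebo_form in ("emax", "sigmoid_emax"):
        x.append(math.log(p.et50))
    if spec.placebo_form == "sigmoid_emax":
        x.append(math.log(p.hill))
    if spec.placebo_form == "exponential":
        x.append(math.log(p.k_onset))
    if spec.placebo_form == "inverse_bateman":
        x += [math.log(p.k_offset), math.log(max(p.k_onset - p.k_offset, 1e-8))]
    for eff in spec.covariate_effects:
        x.append(theta_map.get(eff.key, eff.theta))
    if spec.estimate_omega_alpha:
        x.append(math.log(max(p.omega_alpha, 1e-8)))
    if spec.estimate_omega_beta:
        x.append(math.log(max(p.omega_beta, 1e-8)))
    if spec.estimate_omega_alpha and spec.estimate_omega_beta and spec.estimate_rho:
        x.append(math.atanh(np.clip(p.rho, -0.999999, 0.999999)))
    x.append(math.log(p.delta))
    return np.array(x, dtype=float)


def unpack(x: np.ndarray, spec: ModelSpec) -> PopulationParameters:
    """Unconstrained vector -> natural PopulationParameters."""
    it = iter(x)
    alpha, beta = next(it), next(it)
    et50, hill, k_on, k_off = 8.0, 1.0, 0.2, 0.05
    if spec.placebo_form in ("emax", "sigmoid_emax"):
        et50 = math.exp(next(it))
    if spec.placebo_form == "sigmoid_emax":
        hill = math.exp(next(it))
    if spec.placebo_form == "exponential":
        k_on = math.exp(next(it))
    if spec.placebo_form == "inverse_bateman":
        k_off = math.exp(next(it))
        k_on = k_off + math.exp(next(it))
    effects = tuple(replace(eff, theta=float(next(it)))
                    for eff in spec.covariate_effects)
    om_a = math.exp(next(it)) if spec.estimate_omega_alpha else spec.omega_alpha_fixed
    om_b = math.exp(next(it)) if spec.estimate_omega_beta else spec.omega_beta_fixed
    if spec.estimate_omega_alpha and spec.estimate_omega_beta and spec.estimate_rho:
        rho = math.tanh(next(it))
    else:
        rho = spec.rho_fixed
    delta = math.exp(next(it))
    return PopulationParameters(
        alpha_typ=alpha, beta_typ=beta, et50=et50, hill=hill,
        k_onset=k_on, k_offset=k_off,
        omega_alpha=om_a, omega_beta=om_b, rho=rho, delta=delta,
        placebo_form=spec.placebo_form, covariate_effects=effects)


def natural_vector(p: PopulationParameters, spec: ModelSpec):
    """Natural-scale parameter vector and its names (for delta-method SEs)."""
    names = ["alpha", "beta"]
    vals = [p.alpha_typ, p.beta_typ]
    if spec.placebo_form in ("emax", "sigmoid_emax"):
        names.append("et50"); vals.append(p.et50)
    if spec.placebo_form == "sigmoid_emax":
        names.append("hill"); vals.append(p.hill)
    if spec.placebo_form == "exponential":
        names.append("k_onset"); vals.append(p.k_onset)
    if spec.placebo_form == "inverse_bateman":
        names += ["k_offset", "k_onset"]; vals += [p.k_offset, p.k_onset]
    for eff in p.covariate_effects:
        names.append(f"theta[{eff.covariate}->{eff.parameter}]")
        vals.append(eff.theta)
    if spec.estimate_omega_alpha:
        names.append("omega_alpha"); vals.append(p.omega_alpha)
    if spec.estimate_omega_beta:
        names.append("omega_beta"); vals.append(p.omega_beta)
    if spec.estimate_omega_alpha and spec.estimate_omega_beta and spec.estimate_rho:
        names.append("rho"); vals.append(p.rho)
    names.append("delta"); vals.append(p.delta)
    return np.array(vals), names


# ---------------------------------------------------------------------------
# design cache

class Design:
    """Padded per-study arrays (studies x max-observations) plus covariates."""

    def __init__(self, ts: TrialSet, spec: ModelSpec):
        self.study_ids = [a.study_id for a in ts.arms]
        S = len(ts.arms)
        if S == 0:
            raise ValueError("empty trial set")
        M = max(len(a.observations) for a in ts.arms)
        self.t = np.zeros((S, M))
        self.y = np.zeros((S, M))
        self.n = np.ones((S, M))
        self.mask = np.zeros((S, M))
        for i, arm in enumerate(ts.arms):
            m = len(arm.observations)
            if m == 0:
                raise ValueError(f"arm {arm.study_id} has no observations")
            self.t[i, :m] = [o.time for o in arm.observations]
            self.y[i, :m] = [o.mean_change for o in arm.observations]
            self.n[i, :m] = [o.n for o in arm.observations]
            self.mask[i, :m] = 1.0
        self.m_per_study = self.mask.sum(axis=1)
        self.cov = {}
        for eff in spec.covariate_effects:
            vals = np.array([a.covariate(eff.covariate) for a in ts.arms])
            if not np.all(np.isfinite(vals)):
                bad = [ts.arms[i].study_id for i in np.flatnonzero(~np.isfinite(vals))]
                raise ValueError(
                    f"covariate {eff.covariate!r} missing for studies {bad[:5]}")
            self.cov[eff.covariate] = vals


def _mean_and_columns(d: Design, p: PopulationParameters):
    """Typical mean mu and random-effect design columns (x_alpha, x_beta)."""
    g = placebo_time_profile(d.t, p)
    fa = np.ones(len(d.study_ids))
    fb = np.ones(len(d.study_ids))
    for eff in p.covariate_effects:
        f = covariate_multiplier(d.cov[eff.covariate], eff.ref, eff.theta,
                                 eff.form, eff.scale_max, name=eff.covariate)
        if eff.parameter == "alpha":
            fa = fa * f
        else:
            fb = fb * f
    A = p.alpha_typ * fa
    B = p.beta_typ * fb
    x_alpha = A[:, None] * d.t * d.mask
    x_beta = B[:, None] * g * d.mask
    mu = (x_alpha + x_beta)
    return mu, x_alpha, x_beta, A, B


class _LaplaceState:
    """Everything the Laplace factorisation computes, kept for reuse by
    empirical-Bayes extraction and diagnostics."""

    __slots__ = ("ofv", "per_study", "eta_hat", "eta_cov", "mu", "A", "B",
                 "active", "resid_cond")

    def __init__(self):
        self.ofv = np.inf


def _laplace_state(d: Design, p: PopulationParameters) -> _LaplaceState:
    st = _LaplaceState()
    mu, x_a, x_b, A, B = _mean_and_columns(d, p)
    S = mu.shape[0]
    r = (d.y - mu) * d.mask
    W = d.mask * d.n / p.delta**2
    base = d.m_per_study * _LOG2PI + np.sum(
        d.mask * np.log(p.delta**2 / d.n), axis=1)

    active = [i for i, om in enumerate((p.omega_alpha, p.omega_beta)) if om > 0]
    st.active = active
    st.mu, st.A, st.B = mu, A, B
    st.eta_hat = np.zeros((S, 2))
    st.eta_cov = np.zeros((S, 2, 2))

    if not active:
        per = base + np.sum(W * r**2, axis=1)
        st.per_study = per
        st.resid_cond = r
        st.ofv = float(np.sum(per))
        return st

    cols = [x_a, x_b]
    X = np.stack([cols[i] for i in active], axis=2)          # (S, M, d)
    Om = p.omega_matrix()[np.ix_(active, active)]
    try:
        Om_inv = np.linalg.inv(Om)
        sign, logdet_Om = np.linalg.slogdet(Om)
        if sign <= 0:
            return st
    except np.linalg.LinAlgError:
        return st

    XtW = X * W[:, :, None]
    G = np.einsum("smd,sme->sde", XtW, X)
    b = np.einsum("smd,sm->sd", XtW, r)
    H = Om_inv[None, :, :] + G
    try:
        eta = np.linalg.solve(H, b[:, :, None])[:, :, 0]     # (S, d)
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return st
    rhat = r - np.einsum("smd,sd->sm", X, eta)
    quad = np.sum(W * rhat**2, axis=1) + np.einsum(
        "sd,de,se->s", eta, Om_inv, eta)
    sign_h, logdet_H = np.linalg.slogdet(H)
    if np.any(sign_h <= 0):
        return st
    per = base + quad + logdet_Om + logdet_H
    st.per_study = per
    st.resid_cond = rhat
    for j, dim in enumerate(active):
        st.eta_hat[:, dim] = eta[:, j]
        for k, dim2 in enumerate(active):
            st.eta_cov[:, dim, dim2] = Hinv[:, j, k]
    st.ofv = float(np.sum(per))
    return st


def _neg2ll_foce(d: Design, p: PopulationParameters) -> float:
    """Marginalised Gaussian objective via batched Cholesky on
    Sigma = X Omega X' + D (independent route; equals Laplace here)."""
    mu, x_a, x_b, _, _ = _mean_and_columns(d, p)
    S, M = mu.shape
    r = (d.y - mu) * d.mask
    dvec = np.where(d.mask > 0, p.delta**2 / d.n, 1.0)  # pad slots: unit var, r = 0
    X = np.stack([x_a, x_b], axis=2)
    Om = p.omega_matrix()
    Sigma = np.einsum("smd,de,spe->smp", X, Om, X)
    Sigma[:, np.arange(M), np.arange(M)] += dvec
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    sol = np.linalg.solve(Sigma, r[:, :, None])[:, :, 0]
    quad = np.sum(r * sol, axis=1)
    per = d.m_per_study * _LOG2PI + logdet + quad
    return float(np.sum(per))


def _profile_and_dlog(d: Design, p: PopulationParameters):
    """g(t) and its derivatives w.r.t. the log-scale shape parameters.

    Returns (g, {name: dg/dlog(param)}); analytic forms exist for the
    Emax, sigmoid-Emax and exponential profiles.
    """
    t = d.t
    if p.placebo_form == "emax":
        g = t / (p.et50 + t)
        return g, {"log_et50": -g * (1.0 - g)}
    if p.placebo_form == "sigmoid_emax":
        h = p.hill
        tsafe = np.where(d.mask > 0, t, 1.0)
        th = tsafe**h
        g = np.where(d.mask > 0, th / (p.et50**h + th), 0.0)
        g1g = g * (1.0 - g)
        return g, {
            "log_et50": -h * g1g,
            "log_hill": np.where(d.mask > 0,
                                 h * np.log(tsafe / p.et50) * g1g, 0.0),
        }
    if p.placebo_form == "exponential":
        kt = p.k_onset * t
        g = 1.0 - np.exp(-kt)
        return g, {"log_k_onset": kt * np.exp(-kt)}
    raise NotImplementedError(p.placebo_form)


def _value_and_grad(d: Design, p: PopulationParameters, spec: ModelSpec):
    """-2 log marginal likelihood and its gradient on the transformed
    parameter scale, via the marginal Gaussian form Sigma = X Omega X' + D.

    For each parameter theta the standard identity applies:
    d(-2ll) = tr(K dSigma) - q' dSigma q - 2 dmu' q with K = Sigma^-1
    and q = K r.  Padded observation slots carry unit variance, zero
    residual and zero design rows, so they contribute nothing.
    """
    g, dg_map = _profile_and_dlog(d, p)
    S, M = d.t.shape
    fa = np.ones(S)
    fb = np.ones(S)
    logkernels = []
    for eff in p.covariate_effects:
        vals = d.cov[eff.covariate]
        f = covariate_multiplier(vals, eff.ref, eff.theta, eff.form,
                                 eff.scale_max, name=eff.covariate)
        if eff.form in ("power", "inverse_u"):
            # factor = kernel**theta; d factor/d theta = factor*log(kernel)
            logk = np.log(f) / eff.theta if eff.theta != 0 else (
                np.log(vals / eff.ref) if eff.form == "power"
                else np.log((vals / eff.ref) * (eff.scale_max - vals)
                            / (eff.scale_max - eff.ref)))
        else:
            # linear/indicator: factor = 1 + theta*z; d/dtheta = z
            z = (vals / eff.ref - 1.0 if eff.form == "linear"
                 else vals - eff.ref)
            logk = z / f  # d log factor / d theta
        logkernels.append((eff, logk))
        if eff.parameter == "alpha":
            fa = fa * f
        else:
            fb = fb * f

    xa_unit = fa[:, None] * d.t * d.mask       # d mu / d alpha
    xb_unit = fb[:, None] * g * d.mask         # d mu / d beta
    x_a = p.alpha_typ * xa_unit
    x_b = p.beta_typ * xb_unit
    mu = x_a + x_b
    r = (d.y - mu) * d.mask
    X = np.stack([x_a, x_b], axis=2)           # (S, M, 2)
    Om = p.omega_matrix()
    dvec = np.where(d.mask > 0, p.delta**2 / d.n, 1.0)
    Sigma = np.einsum("smd,de,spe->smp", X, Om, X)
    idx = np.arange(M)
    Sigma[:, idx, idx] += dvec
    try:
        K = np.linalg.inv(Sigma)
        sign, logdet = np.linalg.slogdet(Sigma)
    except np.linalg.LinAlgError:
        return np.inf, None
    if np.any(sign <= 0):
        return np.inf, None
    q = np.einsum("smp,sp->sm", K, r)
    val = float(np.sum(d.m_per_study * _LOG2PI + logdet + np.sum(r * q, axis=1)))

    U = X @ Om                                  # (S, M, 2)
    KU = np.einsum("smp,spe->sme", K, U)
    Xq = np.einsum("smd,sm->sd", X, q)          # (S, 2)
    Uq = np.einsum("smd,sm->sd", U, q)

    def from_dX(dxcol, which):
        # dSigma = dxcol (X Omega)_col' + (X Omega)_col dxcol'
        tr = 2.0 * np.sum(KU[:, :, which] * dxcol)
        quad = 2.0 * np.sum(np.sum(q * dxcol, axis=1) * Uq[:, which])
        return tr - quad

    def from_dmu(dmu):
        return -2.0 * np.sum(dmu * q)

    grads = {}
    # fixed effects alpha, beta: mu and the matching X column both move
    grads["alpha"] = from_dmu(xa_unit) + from_dX(xa_unit, 0)
    grads["beta"] = from_dmu(xb_unit) + from_dX(xb_unit, 1)
    # nonlinear shape parameters (log scale): mu and X column 1 move
    for name, dg in dg_map.items():
        dmu = p.beta_typ * fb[:, None] * dg * d.mask
        grads[name] = from_dmu(dmu) + from_dX(dmu, 1)
    # covariate coefficients: scale the study factor, moving mu and X
    for eff, logk in logkernels:
        if eff.parameter == "alpha":
            dmu = logk[:, None] * x_a
            val_g = from_dmu(dmu) + from_dX(dmu, 0)
        else:
            dmu = logk[:, None] * x_b
            val_g = from_dmu(dmu) + from_dX(dmu, 1)
        grads[f"theta[{eff.covariate}->{eff.parameter}:{eff.form}]"] = val_g
    # variance components: Sigma only
    XtKX = np.einsum("smd,smp,spe->sde", X, K, X)
    oa, ob, rho = p.omega_alpha, p.omega_beta, p.rho

    def from_dOm(dOm):
        tr = np.sum(XtKX * dOm[None, :, :])
        quad = np.einsum("sd,de,se->", Xq, dOm, Xq)
        return tr - quad

    if spec.estimate_omega_alpha:
        dOm = np.array([[2 * oa**2, rho * oa * ob], [rho * oa * ob, 0.0]])
        grads["log_omega_alpha"] = from_dOm(dOm)
    if spec.estimate_omega_beta:
        dOm = np.array([[0.0, rho * oa * ob], [rho * oa * ob, 2 * ob**2]])
        grads["log_omega_beta"] = from_dOm(dOm)
    if spec.estimate_omega_alpha and spec.estimate_omega_beta and spec.estimate_rho:
        dOm = (1.0 - rho**2) * oa * ob * np.array([[0.0, 1.0], [1.0, 0.0]])
        grads["atanh_rho"] = from_dOm(dOm)
    ddiag = np.where(d.mask > 0, 2.0 * p.delta**2 / d.n, 0.0)
    Kdiag = np.diagonal(K, axis1=1, axis2=2)
    grads["log_delta"] = float(np.sum(Kdiag * ddiag) - np.sum(q**2 * ddiag))

    grad = np.array([grads[name] for name in spec.transformed_names])
    return val, grad


def _neg2ll_agq(d: Design, p: PopulationParameters, nodes: int = 15) -> float:
    """Adaptive Gauss-Hermite quadrature oracle (product grid per study)."""
    from numpy.polynomial.hermite import hermgauss
    st = _laplace_state(d, p)
    mu, x_a, x_b, _, _ = _mean_and_columns(d, p)
    r0 = (d.y - mu) * d.mask
    W = d.mask * d.n / p.delta**2
    base = d.m_per_study * _LOG2PI + np.sum(d.mask * np.log(p.delta**2 / d.n), axis=1)
    active = st.active
    ndim = len(active)
    if ndim == 0:
        return float(np.sum(base + np.sum(W * r0**2, axis=1)))

    z, w = hermgauss(nodes)
    logw = np.log(w)
    if ndim == 1:
        grid = z[:, None]
        logw_grid = logw
    else:
        grid = np.stack(np.meshgrid(z, z, indexing="ij"), axis=-1).reshape(-1, 2)
        logw_grid = (logw[:, None] + logw[None, :]).reshape(-1)

    Om = p.omega_matrix()[np.ix_(active, active)]
    Om_inv = np.linalg.inv(Om)
    _, logdet_Om = np.linalg.slogdet(Om)
    cols = [x_a, x_b]
    X = np.stack([cols[i] for i in active], axis=2)

    total = 0.0
    for i in range(mu.shape[0]):
        Hi = np.linalg.inv(st.eta_cov[i][np.ix_(active, active)])
        L = np.linalg.cholesky(Hi)
        eta0 = st.eta_hat[i, active]
        # eta = eta0 + sqrt(2) * L^-T u; d(eta) = 2^{d/2} |L|^-1 du
        shift = math.sqrt(2.0) * np.linalg.solve(L.T, grid.T).T
        etas = eta0[None, :] + shift
        resid = r0[i][None, :] - etas @ X[i].T
        log_dens = (-0.5 * (base[i] + np.sum(W[i][None, :] * resid**2, axis=1))
                    - 0.5 * (ndim * _LOG2PI + logdet_Om
                             + np.einsum("kd,de,ke->k", etas, Om_inv, etas)))
        log_terms = log_dens + np.sum(grid**2, axis=1) + logw_grid
        m = np.max(log_terms)
        log_int = (m + math.log(np.sum(np.exp(log_terms - m)))
                   + 0.5 * ndim * math.log(2.0)
                   - np.sum(np.log(np.diag(L))))
        total += -2.0 * log_int
    return float(total)


def neg2ll(ts: TrialSet, p: PopulationParameters, spec: ModelSpec | None = None,
           method: str = "laplace", agq_nodes: int = 15,
           design: Design | None = None) -> float:
    """-2 log approximate marginal likelihood (OFV) of a parameter set.

    Study contributions are independent and summed; with all omegas zero
    the value reduces to the closed-form sqrt(N)-weighted least-squares
    deviance.
    """
    if spec is None:
        spec = ModelSpec(placebo_form=p.placebo_form,
                         covariate_effects=p.covariate_effects)
    d = design if design is not None else Design(ts, spec)
    if method == "laplace":
        return _laplace_state(d, p).ofv
    if method == "foce":
        return _neg2ll_foce(d, p)
    if method == "agq":
        if agq_nodes < 9:
            raise ValueError("agq oracle requires >= 9 nodes per dimension")
        return _neg2ll_agq(d, p, nodes=agq_nodes)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    """Maximum-likelihood fit of one model specification."""

    estimates: PopulationParameters
    spec: ModelSpec
    ofv: float
    aic: float
    converged: bool
    message: str
    n_studies: int
    n_obs: int
    n_params: int
    param_names: list[str] = field(default_factory=list)
    se: dict = field(default_factory=dict)
    rse_percent: dict = field(default_factory=dict)
    vcov: pd.DataFrame | None = None
    ebe: pd.DataFrame | None = None
    shrinkage: dict = field(default_factory=dict)
    x_opt: np.ndarray | None = None
    n_evals: int = 0
    seed: int = 0

    def parameter_table(self, include_rho_se: bool = False) -> pd.DataFrame:
        """Estimate / RSE% / Wald 95% CI table on the natural scale.

        The random-effect correlation is reported as a derived Pearson
        correlation without an SE unless ``include_rho_se``.
        """
        vals, names = natural_vector(self.estimates, self.spec)
        rows = []
        for name, val in zip(names, vals):
            se = self.se.get(name, math.nan)
            if name == "rho" and not include_rho_se:
                se = math.nan
            rse = 100.0 * se / abs(val) if np.isfinite(se) and val != 0 else math.nan
            lo, hi = (val - 1.96 * se, val + 1.96 * se) if np.isfinite(se) \
                else (math.nan, math.nan)
            rows.append({"parameter": name, "estimate": val, "rse_percent": rse,
                         "ci95_low": lo, "ci95_high": hi})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        vals, names = natural_vector(self.estimates, self.spec)
        return {
            "placebo_form": self.spec.placebo_form,
            "covariate_effects": [
                {"covariate": e.covariate, "parameter": e.parameter,
                 "form": e.form, "theta": e.theta, "ref": e.ref}
                for e in self.estimates.covariate_effects],
            "estimates": {n: float(v) for n, v in zip(names, vals)},
            "se": {k: (None if not np.isfinite(v) else float(v))
                   for k, v in self.se.items()},
            "ofv": self.ofv, "aic": self.aic, "converged": self.converged,
            "message": self.message, "n_studies": self.n_studies,
            "n_obs": self.n_obs, "n_params": self.n_params,
            "seed": self.seed, "n_evals": self.n_evals,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _heuristic_starts(d: Design, spec: ModelSpec) -> np.ndarray:
    """Data-driven starting values: (alpha, beta) from a weighted linear
    regression on [t, t/(8+t)], delta from its residual scale."""
    msk = d.mask > 0
    t = d.t[msk]
    y = d.y[msk]
    n = d.n[msk]
    g8 = t / (8.0 + t)
    Xd = np.column_stack([t, g8])
    sw = np.sqrt(n)
    coef, *_ = np.linalg.lstsq(Xd * sw[:, None], y * sw, rcond=None)
    alpha0, beta0 = float(coef[0]), float(coef[1])
    if not np.isfinite(alpha0):
        alpha0 = 0.1
    if not np.isfinite(beta0) or beta0 == 0:
        beta0 = -1.0
    resid = y - Xd @ coef
    delta0 = float(np.sqrt(np.mean(n * resid**2)))
    delta0 = min(max(delta0, 0.5), 50.0)
    p0 = PopulationParameters(
        alpha_typ=alpha0, beta_typ=beta0, et50=8.0, hill=1.0,
        k_onset=0.2, k_offset=0.05,
        omega_alpha=0.2, omega_beta=0.5, rho=-0.3, delta=delta0,
        placebo_form=spec.placebo_form,
        covariate_effects=tuple(replace(e, theta=e.theta)
                                for e in spec.covariate_effects))
    return pack(p0, spec)


def _jitter(x: np.ndarray, names: Sequence[str], rng: np.random.Generator) -> np.ndarray:
    """Multi-start perturbation: multiply natural values by up to x/÷ 3."""
    out = x.copy()
    for i, name in enumerate(names):
        u = rng.uniform(-math.log(3.0), math.log(3.0))
        if name.startswith("log_"):
            out[i] += u
        elif name.startswith("atanh_"):
            out[i] += rng.uniform(-0.5, 0.5)
        else:
            out[i] *= math.exp(u)
    return out


def fit(ts: TrialSet, spec: ModelSpec, starts=None, n_restarts: int = 3,
        seed: int = 0, compute_se: bool = True, compute_ebe: bool = True,
        maxiter: int = 500, ftol: float = 1e-12, gtol: float = 1e-7) -> FitResult:
    """Maximum (approximate) marginal-likelihood fit of ``spec``.

    ``starts`` may be ``None`` (data-driven heuristics), a
    ``PopulationParameters`` (warm start) or a transformed vector.  The
    best of ``n_restarts`` multi-starts is kept; the jitter stream is
    seeded so the fit is deterministic given (data, spec, starts, seed).
    """
    d = Design(ts, spec)
    names = spec.transformed_names
    if starts is None:
        x0 = _heuristic_starts(d, spec)
    elif isinstance(starts, PopulationParameters):
        x0 = pack(starts, spec)
    else:
        x0 = np.asarray(starts, dtype=float)
    if x0.size != len(names):
        raise ValueError(f"starts have length {x0.size}, expected {len(names)}")

    evals = [0]

    def objective(x):
        evals[0] += 1
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                val = _laplace_state(d, unpack(x, spec)).ofv
        except (ValueError, FloatingPointError, OverflowError):
            return _BIG
        if not np.isfinite(val):
            return _BIG
        return val

    # analytic gradients exist for the profiles with closed-form shape
    # derivatives; the inverse Bateman form falls back to finite
    # differences
    use_grad = spec.placebo_form in ("emax", "sigmoid_emax", "exponential")
    zero_grad = np.zeros(len(names))

    def objective_grad(x):
        evals[0] += 1
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                val, grad = _value_and_grad(d, unpack(x, spec), spec)
        except (ValueError, FloatingPointError, OverflowError):
            return _BIG, zero_grad
        if (grad is None or not np.isfinite(val)
                or not np.all(np.isfinite(grad))):
            return _BIG, zero_grad
        return val, grad

    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_restarts)):
        xk = x0 if k == 0 else _jitter(x0, names, rng)
        if use_grad:
            res = minimize(objective_grad, xk, method="L-BFGS-B", jac=True,
                           options={"maxiter": maxiter, "ftol": ftol,
                                    "gtol": gtol})
        else:
            res = minimize(objective, xk, method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": ftol,
                                    "gtol": gtol})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    converged = bool(best.fun < _BIG / 2 and np.all(np.isfinite(best.x)))
    p_hat = unpack(best.x, spec)
    ofv = float(best.fun)
    npar = len(names)
    fr = FitResult(
        estimates=p_hat, spec=spec, ofv=ofv, aic=ofv + 2.0 * npar,
        converged=converged, message=str(best.message),
        n_studies=len(ts.arms), n_obs=int(np.sum(d.mask)), n_params=npar,
        x_opt=best.x.copy(), n_evals=evals[0], seed=seed)
    _, nat_names = natural_vector(p_hat, spec)
    fr.param_names = nat_names

    if compute_se and converged:
        _attach_se(fr, d, spec, best.x, objective)
    if compute_ebe and converged:
        ebe, shr = _ebe_frame(d, p_hat)
        fr.ebe = ebe
        fr.shrinkage = shr
    return fr


def _attach_se(fr: FitResult, d: Design, spec: ModelSpec, x_opt: np.ndarray,
               objective) -> None:
    """Observed-information SEs, delta-method back-transformed."""
    try:
        H = approx_hess(x_opt, objective)
        cov_t = 2.0 * np.linalg.inv(H)          # objective is -2 log L
        J = approx_fprime(x_opt,
                          lambda x: natural_vector(unpack(x, spec), spec)[0])
        cov_n = J @ cov_t @ J.T
    except np.linalg.LinAlgError:
        logger.warning("Hessian not invertible; SEs unavailable")
        return
    if not np.all(np.isfinite(cov_n)):
        logger.warning("non-finite Hessian; SEs unavailable")
        return
    _, names = natural_vector(fr.estimates, spec)
    var = np.diag(cov_n).copy()
    se = np.where(var > 0, np.sqrt(np.abs(var)), math.nan)
    fr.se = dict(zip(names, se))
    vals, _ = natural_vector(fr.estimates, spec)
    fr.rse_percent = {n: (100.0 * s / abs(v) if np.isfinite(s) and v != 0
                          else math.nan)
                      for n, v, s in zip(names, vals, se)}
    fr.vcov = pd.DataFrame(cov_n, index=names, columns=names)


def _ebe_frame(d: Design, p: PopulationParameters):
    """Per-study empirical-Bayes eta modes, conditional SDs, individual
    parameters and shrinkage statistics."""
    st = _laplace_state(d, p)
    if not np.isfinite(st.ofv):
        raise RuntimeError("likelihood not finite at the supplied estimates")
    sd_a = np.sqrt(np.maximum(st.eta_cov[:, 0, 0], 0.0))
    sd_b = np.sqrt(np.maximum(st.eta_cov[:, 1, 1], 0.0))
    alpha_i = st.A * (1.0 + st.eta_hat[:, 0])
    beta_i = st.B * (1.0 + st.eta_hat[:, 1])
    frame = pd.DataFrame({
        "study_id": d.study_ids,
        "eta_alpha": st.eta_hat[:, 0],
        "eta_beta": st.eta_hat[:, 1],
        "sd_eta_alpha": sd_a,
        "sd_eta_beta": sd_b,
        "alpha_i": alpha_i,
        "beta_i": beta_i,
        "se_alpha_i": np.abs(st.A) * sd_a,
        "se_beta_i": np.abs(st.B) * sd_b,
    })
    shrink = {}
    for label, col, om in (("alpha", "eta_alpha", p.omega_alpha),
                           ("beta", "eta_beta", p.omega_beta)):
        if om > 0 and len(frame) > 1:
            shrink[label] = float(1.0 - np.std(frame[col], ddof=1) / om)
        else:
            shrink[label] = 1.0
    return frame, shrink


def empirical_bayes(ts: TrialSet, fr: FitResult) -> pd.DataFrame:
    """Per-study (alpha_i, beta_i) posterior modes with conditional SEs.

    SEs come from the conditional Hessian at the eta mode via the delta
    method; shrinkage (1 - SD(eta_hat)/omega) is stored in
    ``frame.attrs['shrinkage']``.
    """
    if not fr.converged:
        raise ValueError("empirical Bayes requires a converged fit")
    d = Design(ts, fr.spec)
    frame, shrink = _ebe_frame(d, fr.estimates)
    frame.attrs["shrinkage"] = shrink
    return frame


def select_structural(ts: TrialSet, forms: Sequence[str] = (
        "emax", "sigmoid_emax", "exponential", "inverse_bateman"),
        n_restarts: int = 2, seed: int = 0, **fit_kw) -> pd.DataFrame:
    """Fit each candidate placebo-effect form and rank by AIC.

    Non-converging candidates (the inverse Bateman form routinely fails
    on short-duration designs, where its washout rate is unidentified)
    are listed last with the failure reason.
    """
    if len(forms) < 2:
        raise ValueError("need at least two candidate forms")
    rows = []
    for pos, form in enumerate(forms):
        spec = base_model_spec(form)
        try:
            fr = fit(ts, spec, n_restarts=n_restarts, seed=seed,
                     compute_se=False, compute_ebe=False, **fit_kw)
            rows.append({"form": form, "position": pos, "ofv": fr.ofv,
                         "aic": fr.aic, "converged": fr.converged,
                         "n_params": fr.n_params, "message": fr.message})
        except Exception as exc:  # a failed candidate is data, not an error
            rows.append({"form": form, "position": pos, "ofv": math.nan,
                         "aic": math.nan, "converged": False,
                         "n_params": spec.n_parameters, "message": str(exc)})
    table = pd.DataFrame(rows)
    table["rank_key"] = np.where(table["converged"], table["aic"], np.inf)
    table = table.sort_values(["rank_key", "position"], kind="stable")
    return table.drop(columns="rank_key").reset_index(drop=True)
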