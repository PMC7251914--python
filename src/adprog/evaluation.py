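"""Model evaluation: nonparametric bootstrap, visual predictive check and
goodness-of-fit diagnostics.

The resampling unit of the bootstrap is the study arm — the model's
exchangeable unit under study-level random effects.  The VPC simulates
replicate datasets on the observed design (same studies, visit times,
sample sizes and covariates) from the fitted parameters, and compares
observed quantiles per time bin with their simulated confidence bands.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialSet
from .estimation import (
    Design,
    FitResult,
    ModelSpec,
    _laplace_state,
    _mean_and_columns,
    fit,
    natural_vector,
)

__all__ = ["BootstrapResult", "VPCResult", "bootstrap", "vpc", "diagnostics"]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Replicate-level estimates plus median / 95% percentile summary."""

    replicates: pd.DataFrame      # one row per converged replicate
    summary: pd.DataFrame         # parameter, median, pi95_low, pi95_high
    n_requested: int
    n_failed: int
    seed: int
    unreliable: bool = False

    @property
    def n_converged(self) -> int:
        return len(self.replicates)


def bootstrap(ts: TrialSet, spec: ModelSpec, B: int = 1000, seed: int = 0,
              reference_fit: FitResult | None = None,
              **fit_kw) -> BootstrapResult:
    """Nonparametric bootstrap: resample studies with replacement to the
    original study count and refit each replicate dataset.

    Replicate fits warm-start at the original estimates with one
    jittered fallback.  Failures are logged and excluded from the
    summary but reported in the denominator; a result with more than
    half of its replicates failed is flagged unreliable.
    """
    if reference_fit is None:
        reference_fit = fit(ts, spec, seed=seed, compute_se=False,
                            compute_ebe=False, **fit_kw)
    S = len(ts.arms)
    fit_kw.setdefault("n_restarts", 2)
    # replicate fits are warm-started summaries, not reported estimates:
    # a looser optimizer tolerance costs << the percentile Monte-Carlo error
    fit_kw.setdefault("ftol", 1e-9)
    fit_kw.setdefault("gtol", 1e-4)
    rng = np.random.default_rng(seed)
    rows, n_failed = [], 0
    for b in range(B):
        idx = rng.integers(0, S, size=S)
        boot = TrialSet(
            arms=[_relabel(ts.arms[i], pos) for pos, i in enumerate(idx)],
            covariate_refs=dict(ts.covariate_refs))
        try:
            fr = fit(boot, spec, starts=reference_fit.estimates,
                     seed=seed + b + 1,
                     compute_se=False, compute_ebe=False, **fit_kw)
        except Exception as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            n_failed += 1
            continue
        if not fr.converged:
            n_failed += 1
            continue
        vals, names = natural_vector(fr.estimates, spec)
        rows.append({"replicate": b, **dict(zip(names, vals))})
    reps = pd.DataFrame(rows)
    if len(reps):
        params = [c for c in reps.columns if c != "replicate"]
        summary = pd.DataFrame({
            "parameter": params,
            "median": [reps[c].median() for c in params],
            "pi95_low": [reps[c].quantile(0.025) for c in params],
            "pi95_high": [reps[c].quantile(0.975) for c in params],
        })
    else:
        summary = pd.DataFrame(columns=["parameter", "median",
                                        "pi95_low", "pi95_high"])
    return BootstrapResult(replicates=reps, summary=summary, n_requested=B,
                           n_failed=n_failed, seed=seed,
                           unreliable=n_failed > B / 2)


def _relabel(arm, pos):
    # duplicated draws need unique ids to keep the TrialSet invariant
    from dataclasses import replace
    return replace(arm, study_id=f"B{pos:03d}_{arm.study_id}")


@dataclass
class VPCResult:
    """Observed quantiles per time bin with simulated 95% CI bands."""

    table: pd.DataFrame
    n_sim: int
    seed: int
    quantiles: tuple[float, ...] = (0.025, 0.5, 0.975)

    def coverage(self) -> dict[str, float]:
        """Fraction of bins whose observed quantile lies inside its
        simulated band, per quantile."""
        out = {}
        for q in ("lo", "med", "hi"):
            inside = ((self.table[f"obs_{q}"] >= self.table[f"sim_{q}_low"])
                      & (self.table[f"obs_{q}"] <= self.table[f"sim_{q}_high"]))
            out[q] = float(inside.mean())
        return out


def _simulate_on_design(d: Design, p, rng) -> np.ndarray:
    """One replicate of arm-mean observations on the observed design."""
    mu, x_a, x_b, _, _ = _mean_and_columns(d, p)
    S = mu.shape[0]
    cov = p.omega_matrix()
    # safe MVN draw tolerating zero variance components
    sd = np.sqrt(np.diag(cov))
    z = rng.standard_normal((S, 2))
    eta = np.empty((S, 2))
    eta[:, 0] = sd[0] * z[:, 0]
    if sd[0] > 0 and sd[1] > 0:
        eta[:, 1] = sd[1] * (p.rho * z[:, 0]
                             + math.sqrt(max(0.0, 1 - p.rho**2)) * z[:, 1])
    else:
        eta[:, 1] = sd[1] * z[:, 1]
    y = (mu + eta[:, [0]] * x_a + eta[:, [1]] * x_b
         + rng.standard_normal(mu.shape) * p.delta / np.sqrt(d.n))
    return y


def vpc(ts: TrialSet, fr: FitResult, n_sim: int = 1000, seed: int = 0,
        bin_width: float | None = None) -> VPCResult:
    """Visual predictive check on the observed design.

    Default binning is exact nominal visit weeks (aggregate data cluster
    on protocol visits); ``bin_width`` switches to fixed-width bins for
    irregular schedules.
    """
    if not fr.converged:
        raise ValueError("VPC requires a converged fit")
    if n_sim < 2:
        warnings.warn("n_sim < 2: simulated bands collapse to a single "
                      "replicate", stacklevel=2)
    p = fr.estimates
    spec = fr.spec
    d = Design(ts, spec)
    msk = d.mask > 0
    times = d.t[msk]
    obs = d.y[msk]
    if bin_width is None:
        bin_ids = times
    else:
        bin_ids = np.floor(times / bin_width) * bin_width + bin_width / 2.0
    uniq = np.unique(bin_ids)
    qs = (0.025, 0.5, 0.975)

    rng = np.random.default_rng(seed)
    sim_q = np.empty((max(n_sim, 1), len(uniq), 3))
    for s in range(max(n_sim, 1)):
        ysim = _simulate_on_design(d, p, rng)[msk]
        for j, u in enumerate(uniq):
            sel = bin_ids == u
            sim_q[s, j] = np.quantile(ysim[sel], qs)

    rows = []
    for j, u in enumerate(uniq):
        sel = bin_ids == u
        oq = np.quantile(obs[sel], qs)
        row = {"bin_time": float(u), "n_obs": int(sel.sum()),
               "obs_lo": oq[0], "obs_med": oq[1], "obs_hi": oq[2]}
        for k, tag in enumerate(("lo", "med", "hi")):
            row[f"sim_{tag}_low"] = float(np.quantile(sim_q[:, j, k], 0.025))
            row[f"sim_{tag}_med"] = float(np.quantile(sim_q[:, j, k], 0.5))
            row[f"sim_{tag}_high"] = float(np.quantile(sim_q[:, j, k], 0.975))
        rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), n_sim=n_sim, seed=seed)


def diagnostics(ts: TrialSet, fr: FitResult) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    PRED is the population prediction (eta = 0), IPRED the individual
    prediction at the empirical-Bayes mode.  WRES = (y - PRED)*sqrt(n)/
    delta; CWRES decorrelates the population residual with the marginal
    covariance of the first-order conditional expansion (which is the
    exact marginal covariance here, the model being linear in eta).
    """
    if not fr.converged:
        raise ValueError("diagnostics require a converged fit")
    p = fr.estimates
    d = Design(ts, fr.spec)
    st = _laplace_state(d, p)
    mu, x_a, x_b, _, _ = _mean_and_columns(d, p)
    ipred = mu + st.eta_hat[:, [0]] * x_a + st.eta_hat[:, [1]] * x_b
    Om = p.omega_matrix()
    X = np.stack([x_a, x_b], axis=2)
    rows = []
    for i, arm in enumerate(ts.arms):
        m = len(arm.observations)
        r = (d.y[i, :m] - mu[i, :m])
        Vi = (X[i, :m] @ Om @ X[i, :m].T
              + np.diag(p.delta**2 / d.n[i, :m]))
        L = np.linalg.cholesky(Vi)
        cwres = np.linalg.solve(L, r)
        for j, o in enumerate(arm.observations):
            rows.append({
                "study_id": arm.study_id, "time": o.time, "n": o.n,
                "observed": o.mean_change,
                "pred": mu[i, j], "ipred": ipred[i, j],
                "wres": r[j] * math.sqrt(o.n) / p.delta,
                "iwres": (o.mean_change - ipred[i, j]) * math.sqrt(o.n) / p.delta,
                "cwres": cwres[j],
            })
    return pd.DataFrame(rows)
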