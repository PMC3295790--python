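"""Empirical-Bayes differential-methylation calling.

Each probe's normalized log-ratio M_p is modeled as a two-component
zero-centered normal scale mixture

    M_p ~ (1 - pi1) N(0, tau0^2 + s2_p)  +  pi1 N(0, tau1^2 + s2_p)

where s2_p is the probe's known intra-sample (pixel-statistics)
variance and tau0^2 < tau1^2 are the shared inter-sample variances of
the null and differential components. (pi1, tau0^2, tau1^2) are fit by
EM on each generation-vs-parental comparison; the posterior probability
of membership in the wide component is the probe's probability of
differential methylation, and a direction call is made at a posterior
threshold (0.80 by default): up if M > 0, down if M < 0, even
otherwise. The posterior depends on |M| only, so calls flip up<->down
under negation of all log-ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

__all__ = ["EBFit", "DegenerateFitError", "fit_eb_mixture", "posterior_diff", "call_differential"]


class DegenerateFitError(ValueError):
    """The input has no variance to fit a mixture to."""


@dataclass
class EBFit:
    """Fitted mixture: differential weight pi1, null and differential
    prior variances, and the EM log-likelihood trace."""

    pi1: float
    tau0_2: float
    tau1_2: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _component_logpdf(M: np.ndarray, s2: np.ndarray, tau2: float) -> np.ndarray:
    v = tau2 + s2
    return -0.5 * (np.log(2 * math.pi * v) + M**2 / v)


#: Minimum tau1^2 / tau0^2 ratio. Without a scale separation the two
#: components are unidentifiable on null data (the likelihood is flat in
#: pi1 as the variances coincide); enforcing a modest ratio drives pi1
#: toward zero when no wide component is present.
MIN_SCALE_RATIO = 4.0


def _optimize_tau2(M2, s2, w, current: float, lower: float, upper: float) -> float:
    """Maximize the weighted component log-likelihood over tau^2 in
    [lower, upper].

    1-D bounded search on log tau^2; falls back to the current value if
    the search does not improve it (generalized-EM guarantee, keeping
    the log-likelihood trace nondecreasing).
    """
    if w.sum() <= 0:
        return current

    def neg_q(log_t):
        v = np.exp(log_t) + s2
        return float(np.sum(w * (0.5 * np.log(v) + M2 / (2 * v))))

    lo = max(lower, 1e-10)
    hi = max(upper, 2 * lo)
    res = minimize_scalar(
        neg_q,
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    candidate = float(np.exp(res.x))
    if neg_q(res.x) <= neg_q(math.log(max(current, 1e-300))):
        return candidate
    return current


def _rescale_tau2(M2, s2, r1, tau0_2, tau1_2, upper):
    """Maximize Q over a common multiplier c applied to both prior
    variances; accepted only when it improves Q (generalized EM)."""

    def neg_q(log_c):
        c = math.exp(log_c)
        v0 = c * tau0_2 + s2
        v1 = c * tau1_2 + s2
        q0 = np.sum((1 - r1) * (0.5 * np.log(v0) + M2 / (2 * v0)))
        q1 = np.sum(r1 * (0.5 * np.log(v1) + M2 / (2 * v1)))
        return float(q0 + q1)

    hi = math.log(max(upper / max(tau1_2, 1e-300), 1.0))
    res = minimize_scalar(
        neg_q, bounds=(-8.0, hi), method="bounded", options={"xatol": 1e-10}
    )
    if neg_q(res.x) < neg_q(0.0):
        c = math.exp(res.x)
        return c * tau0_2, c * tau1_2
    return tau0_2, tau1_2


def fit_eb_mixture(
    signal: pd.DataFrame, max_iter: int = 200, tol: float = 1e-6
) -> EBFit:
    """Fit (pi1, tau0^2, tau1^2) by EM on the ok-flagged probes.

    Initialization: pi1 = 0.05, tau0^2 = 0.25 var(M), tau1^2 = 4 var(M)
    (deterministic given the data). Stops when the log-likelihood gain
    drops below ``tol`` or after ``max_iter`` iterations.
    """
    ok = signal["flag"].to_numpy() == "ok"
    if ok.sum() < 100:
        raise ValueError(f"EB fit needs >= 100 ok-flagged probes, got {ok.sum()}")
    M = signal["M"].to_numpy(float)[ok]
    s2 = np.clip(signal["s2_intra"].to_numpy(float)[ok], 0.0, None)
    var_m = float(np.var(M))
    if var_m == 0 and np.all(s2 == 0):
        raise DegenerateFitError("zero-variance M with zero intra-sample variance")

    pi1 = 0.05
    tau0_2 = max(0.25 * var_m, 1e-8)
    tau1_2 = max(4.0 * var_m, 1e-6)
    upper = max(100.0 * var_m + float(s2.max()), 1.0)
    M2 = M**2

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log0 = math.log(max(1 - pi1, 1e-300)) + _component_logpdf(M, s2, tau0_2)
        log1 = math.log(max(pi1, 1e-300)) + _component_logpdf(M, s2, tau1_2)
        denom = logsumexp(np.vstack([log0, log1]), axis=0)
        trace.append(float(denom.sum()))
        r1 = np.exp(log1 - denom)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        pi1 = float(np.clip(r1.mean(), 1e-6, 1 - 1e-6))
        tau0_2 = _optimize_tau2(M2, s2, 1 - r1, tau0_2, 0.0, tau1_2 / MIN_SCALE_RATIO)
        tau1_2 = _optimize_tau2(M2, s2, r1, tau1_2, MIN_SCALE_RATIO * tau0_2, upper)
        # joint rescale along the constrained ray: coordinate updates can
        # deadlock on the tau1 = ratio * tau0 boundary, which a common
        # multiplier (constraint-preserving) escapes
        tau0_2, tau1_2 = _rescale_tau2(M2, s2, r1, tau0_2, tau1_2, upper)
    return EBFit(pi1, tau0_2, tau1_2, trace, n_iter=it, converged=converged)


def posterior_diff(M, s2, fit: EBFit) -> np.ndarray:
    """Posterior probability of the differential component, elementwise."""
    M = np.asarray(M, float)
    s2 = np.clip(np.asarray(s2, float), 0.0, None)
    log0 = math.log(max(1 - fit.pi1, 1e-300)) + _component_logpdf(M, s2, fit.tau0_2)
    log1 = math.log(max(fit.pi1, 1e-300)) + _component_logpdf(M, s2, fit.tau1_2)
    return np.exp(log1 - np.logaddexp(log0, log1))


def call_differential(
    signal: pd.DataFrame,
    fit: EBFit,
    threshold: float = 0.80,
    generation: str | None = None,
) -> pd.DataFrame:
    """Direction calls at the posterior threshold.

    up if posterior >= threshold and M > 0; down if posterior >=
    threshold and M < 0; even otherwise (including the exact tie
    M = 0). Low-signal probes are called even with a missing posterior.
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    ok = signal["flag"].to_numpy() == "ok"
    M = signal["M"].to_numpy(float)
    s2 = signal["s2_intra"].to_numpy(float)
    post = np.full(len(signal), np.nan)
    post[ok] = posterior_diff(M[ok], s2[ok], fit)
    direction = np.full(len(signal), "even", dtype=object)
    called = ok & (post >= threshold)
    direction[called & (M > 0)] = "up"
    direction[called & (M < 0)] = "down"
    out = pd.DataFrame(
        {
            "probe_id": signal["probe_id"].to_numpy(),
            "M": M,
            "posterior_diff": post,
            "direction": direction,
        }
    )
    if generation is not None:
        out.insert(1, "generation", generation)
    return out
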