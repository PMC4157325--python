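"""Maximum-likelihood fitting of the social decision rule to movement events.

Each observed movement is scored by the probability the fitted rule assigns
to the destination the bird actually chose, given the occupancy it saw.
Under the default ("conditional") convention the choice distribution is
renormalised over the three feeders other than the origin — the likelihood
conditions on the fact that a move happened and scores only where the bird
went.  The alternative ("unconditional") convention scores the observed
destination under the full four-way distribution that includes staying; both
are exposed because the appropriate form depends on how events were
ascertained.  The occupancy context defaults to the arrival window (the
information available when the destination is chosen).

Point estimates maximise the summed log-likelihood over (s, k, a) or
(s_c, s_h, k, a), optimised on log s and log a with box bounds.  Confidence
intervals are profile-likelihood intervals: the set of parameter values
whose re-optimised log-likelihood lies within chi2_1(0.95)/2 = 1.92 of the
maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_expit, logsumexp
from scipy.stats import chi2

from .decision_model import ModelParams, choice_probabilities
from .movement_extraction import MovementEvent

__all__ = [
    "FitResult",
    "event_log_likelihood",
    "total_log_likelihood",
    "null_log_likelihood",
    "fit",
    "profile_ci",
]

LOG_SA_BOUNDS = (-3.0, 6.0)   # s, a in [e^-3, e^6]
K_BOUNDS = (0.0, 5.0)

Convention = Literal["conditional", "unconditional"]
Context = Literal["arrival", "departure"]


@dataclass
class FitResult:
    params: ModelParams
    log_likelihood: float
    n_events: int
    variant: str
    converged: bool
    n_iter: int
    convention: Convention = "conditional"
    context: Context = "arrival"
    species_filter: str | None = None
    ci: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "log_likelihood": self.log_likelihood,
            "n_events": self.n_events,
            "variant": self.variant,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "convention": self.convention,
            "context": self.context,
            "species_filter": self.species_filter,
            "ci": {k: {"low": v[0], "high": v[1], **({"at_bound": v[2]} if len(v) > 2 else {})}
                   for k, v in self.ci.items()} if self.ci else {},
        }


def _event_context(event: MovementEvent, context: Context):
    occ = (event.occupancy_at_arrival if context == "arrival"
           else event.occupancy_at_departure)
    return occ


def event_log_likelihood(params: ModelParams, event: MovementEvent,
                         convention: Convention = "conditional",
                         context: Context = "arrival") -> float:
    """Log-probability of one observed movement under the decision rule."""
    occ = _event_context(event, context)
    if not occ.defined and params.variant == "two-s":
        # an empty patch carries no social information; score is still
        # well defined (all counts zero), so fall through
        pass
    dist = choice_probabilities(params, occ.counts_conspecific,
                                occ.counts_heterospecific)
    p = dist.probabilities
    to = event.to_feeder - 1
    if convention == "unconditional":
        return float(np.log(p[to]))
    keep = np.ones(len(p), dtype=bool)
    keep[event.from_feeder - 1] = False
    return float(np.log(p[to]) - np.log(p[keep].sum()))


def _design(events: Sequence[MovementEvent], context: Context):
    """Stack per-event occupancy counts into arrays for vectorised
    likelihood evaluation.  Events with an undefined context window are
    dropped with a warning (an empty patch gives no density signal)."""
    usable = [e for e in events if _event_context(e, context).defined]
    dropped = len(events) - len(usable)
    if dropped:
        warnings.warn(f"skipping {dropped} events with undefined occupancy")
    if not usable:
        raise ValueError("no usable events for fitting")
    nc = np.stack([_event_context(e, context).counts_conspecific for e in usable])
    nh = np.stack([_event_context(e, context).counts_heterospecific for e in usable])
    to = np.array([e.to_feeder - 1 for e in usable])
    frm = np.array([e.from_feeder - 1 for e in usable])
    return nc, nh, to, frm


def _nll(theta: np.ndarray, variant: str, nc, nh, to, frm,
         convention: Convention) -> float:
    if variant == "two-s":
        lc, lh, k, la = theta
    else:
        ls, k, la = theta
        lc = lh = ls  # single rate applied to both classes equals the rule
        #              on summed counts (exact algebraic identity)
    tc = nc.sum(axis=1, keepdims=True)
    th = nh.sum(axis=1, keepdims=True)
    z = lc * (nc * (1 + k) - k * tc) + lh * (nh * (1 + k) - k * th) - la
    log_scores = log_expit(z)
    rows = np.arange(len(to))
    if convention == "unconditional":
        denom = logsumexp(log_scores, axis=1)
    else:
        masked = log_scores.copy()
        masked[rows, frm] = -np.inf
        denom = logsumexp(masked, axis=1)
    return float(-(log_scores[rows, to] - denom).sum())


def total_log_likelihood(params: ModelParams, events: Sequence[MovementEvent],
                         convention: Convention = "conditional",
                         context: Context = "arrival") -> float:
    nc, nh, to, frm = _design(events, context)
    theta = _pack(params)
    return -_nll(theta, params.variant, nc, nh, to, frm, convention)


def null_log_likelihood(n_events: int, convention: Convention = "conditional",
                        n_feeders: int = 4) -> float:
    """Log-likelihood of the asocial s = 1 rule: every alternative equally
    likely, so each move contributes log(1/3) (conditional) or log(1/4)."""
    n_alt = n_feeders - 1 if convention == "conditional" else n_feeders
    return n_events * math.log(1.0 / n_alt)


def _pack(params: ModelParams) -> np.ndarray:
    if params.variant == "two-s":
        return np.array([math.log(params.s_c), math.log(params.s_h),
                         params.k, math.log(params.a)])
    return np.array([math.log(params.s), params.k, math.log(params.a)])


def _unpack(theta: np.ndarray, variant: str) -> ModelParams:
    if variant == "two-s":
        return ModelParams(s_c=math.exp(theta[0]), s_h=math.exp(theta[1]),
                           k=float(theta[2]), a=math.exp(theta[3]))
    return ModelParams(s=math.exp(theta[0]), k=float(theta[1]),
                       a=math.exp(theta[2]))


def _bounds(variant: str) -> list[tuple[float, float]]:
    if variant == "two-s":
        return [LOG_SA_BOUNDS, LOG_SA_BOUNDS, K_BOUNDS, LOG_SA_BOUNDS]
    return [LOG_SA_BOUNDS, K_BOUNDS, LOG_SA_BOUNDS]


_DEFAULT_START = {"two-s": np.array([math.log(2), math.log(2), 0.05, math.log(2)]),
                  "single-s": np.array([math.log(2), 0.05, math.log(2)])}

_DISPERSED = [0.0, 1.0, 2.5, -1.0, 3.5]  # log-s offsets for fallback starts


def fit(events: Sequence[MovementEvent], variant: str = "two-s",
        species_filter: str | None = None,
        convention: Convention = "conditional", context: Context = "arrival",
        start: ModelParams | None = None, soft_floor: int = 20) -> FitResult:
    """Maximum-likelihood fit of the decision rule to movement events.

    Optimisation runs on (log s or log s_c/log s_h, k, log a) with box
    bounds by L-BFGS-B; on non-convergence five dispersed starts are tried
    and the best is kept.  Deterministic given identical inputs and start.
    """
    if species_filter is not None:
        events = [e for e in events if e.focal_species == species_filter]
    if len(events) < soft_floor:
        warnings.warn(f"only {len(events)} events after filtering; "
                      f"estimates will be unstable")
    nc, nh, to, frm = _design(events, context)
    bounds = _bounds(variant)

    def run(x0):
        return minimize(_nll, x0, args=(variant, nc, nh, to, frm, convention),
                        method="L-BFGS-B", bounds=bounds)

    x0 = _pack(start) if start is not None else _DEFAULT_START[variant]
    res = run(np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]))
    if not res.success:
        candidates = [res]
        for off in _DISPERSED:
            alt = _DEFAULT_START[variant].copy()
            alt[0] = off
            if variant == "two-s":
                alt[1] = off
            candidates.append(run(alt))
        res = min(candidates, key=lambda r: r.fun)

    return FitResult(params=_unpack(res.x, variant),
                     log_likelihood=-float(res.fun),
                     n_events=len(to), variant=variant,
                     converged=bool(res.success), n_iter=int(res.nit),
                     convention=convention, context=context,
                     species_filter=species_filter)


_PARAM_INDEX = {"two-s": {"s_c": 0, "s_h": 1, "k": 2, "a": 3},
                "single-s": {"s": 0, "k": 1, "a": 2}}
_LOG_SCALE = {"s", "s_c", "s_h", "a"}


def profile_ci(events: Sequence[MovementEvent], fit_result: FitResult,
               parameter: str, level: float = 0.95,
               tol: float = 1e-3, max_expand: int = 60) -> tuple[float, float, dict]:
    """Profile-likelihood confidence interval for one parameter.

    The interval is the set of values whose log-likelihood, re-optimising
    all other parameters, lies within chi2_1(level)/2 of the maximum
    (1.92 for 95%).  Endpoints are located by outward expansion followed by
    bisection; an endpoint clipped at a parameter bound is flagged.
    Returns (low, high, flags) on the natural scale.
    """
    variant = fit_result.variant
    idx = _PARAM_INDEX[variant][parameter]
    if species := fit_result.species_filter:
        events = [e for e in events if e.focal_species == species]
    nc, nh, to, frm = _design(events, fit_result.context)
    bounds = _bounds(variant)
    cutoff = chi2.ppf(level, 1) / 2.0
    theta_hat = _pack(fit_result.params)
    nll_hat = _nll(theta_hat, variant, nc, nh, to, frm, fit_result.convention)

    free = [i for i in range(len(theta_hat)) if i != idx]
    free_bounds = [bounds[i] for i in free]

    def profile_nll(value: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        def obj(x_free):
            full = np.empty(len(theta_hat))
            full[idx] = value
            full[free] = x_free
            return _nll(full, variant, nc, nh, to, frm, fit_result.convention)
        res = minimize(obj, warm[free], method="L-BFGS-B", bounds=free_bounds)
        full = np.empty(len(theta_hat))
        full[idx] = value
        full[free] = res.x
        return float(res.fun), full

    lo_b, hi_b = bounds[idx]
    flags = {"lower_at_bound": False, "upper_at_bound": False, "flat": False}
    step0 = max(0.1, abs(theta_hat[idx]) * 0.1)
    endpoints = []
    for direction, bound, flag in ((-1, lo_b, "lower_at_bound"),
                                   (+1, hi_b, "upper_at_bound")):
        warm = theta_hat.copy()
        inner, outer = theta_hat[idx], None
        step = step0
        for _ in range(max_expand):
            trial = inner + direction * step
            if (direction < 0 and trial <= bound) or (direction > 0 and trial >= bound):
                trial = bound
            val, warm = profile_nll(trial, warm)
            if val - nll_hat > cutoff:
                outer = trial
                break
            inner = trial
            if trial == bound:
                flags[flag] = True
                break
            step *= 2
        if outer is None:
            endpoints.append(bound)
            if not flags[flag]:
                flags["flat"] = True
            continue
        # bisection between inner (inside region) and outer (outside)
        warm = theta_hat.copy()
        while abs(outer - inner) > tol:
            mid = 0.5 * (inner + outer)
            val, warm = profile_nll(mid, warm)
            if val - nll_hat > cutoff:
                outer = mid
            else:
                inner = mid
        endpoints.append(0.5 * (inner + outer))

    lo, hi = sorted(endpoints)
    if parameter in _LOG_SCALE:
        lo, hi = math.exp(lo), math.exp(hi)
    return lo, hi, flags
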