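"""Density-conditioned movement probabilities and the asocial null model.

Given the extracted movement events, Bayes' rule turns observed feeder
densities into the probability that a bird arrives at (or leaves) a feeder
holding a share rho of the patch:

    P(A | rho) = P(rho | A) P(A) / P(rho)

with the prior P(A) fixed at 0.25 because the four feeders are identical.
P(rho) is the frequency of densities observed on all feeders across the
event windows; P(rho | A) the frequency of the density at the arrival feeder
at the moment of arrival (P(rho | L) analogously at the origin).

By default the densities entering these curves count the mover itself as
part of the patch, placed at its origin feeder: the mover is a member of the
flock whose spatial distribution the curves condition on, and under this
convention the estimator applied to asocial (uniform-choice) movement data
recovers the theoretical asocial prediction exactly, whatever the flock
composition.  ``include_focal=False`` instead uses the stored focal-removed
vectors verbatim; note that under that reading an asocial mover's curves are
flat at the prior, because the distribution of the *other* birds carries no
information about where an independently placed mover sits.  The
focal-removed vectors themselves remain what the decision-model likelihood
consumes, so a bird is never attracted by its own presence.

The theoretical asocial prediction (TASP) is the null against which the
empirical curves are compared: a uniformly chosen mover sits at a feeder
with probability equal to its density, so P(leave | rho) = rho, and
relocates uniformly among the other three feeders, so
P(arrive | rho) = (1 - rho) / 3.  Uncertainty on the empirical curves is a
delete-d jackknife envelope: the min-max range of the curve recomputed on
many subsamples with a fixed fraction of events removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .movement_extraction import MovementEvent

__all__ = [
    "DensityCurve",
    "default_bin_edges",
    "empirical_density_curves",
    "jackknife_envelope",
    "tasp_curves",
    "curve_standard_errors",
]

PRIOR_ARRIVAL = 0.25


def default_bin_edges(n_bins: int = 11) -> np.ndarray:
    """Equal-width rho bins centred on 0, 1/(n-1), ..., 1."""
    half = 0.5 / (n_bins - 1)
    return np.linspace(-half, 1 + half, n_bins + 1)


@dataclass
class DensityCurve:
    """Binned P(leave | rho) and P(arrive | rho) with sample sizes and an
    optional resampling envelope.  Bins in which no density was ever
    observed are NaN (undefined), not zero."""

    bin_edges: np.ndarray
    p_leave: np.ndarray
    p_arrive: np.ndarray
    n_leave: np.ndarray
    n_arrive: np.ndarray
    prior_arrival: float = PRIOR_ARRIVAL
    envelope: dict | None = None

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _usable(events: Sequence[MovementEvent], include_focal: bool) -> list[MovementEvent]:
    if include_focal:
        return list(events)  # the focal itself guarantees a non-empty patch
    return [e for e in events
            if e.occupancy_at_departure.defined and e.occupancy_at_arrival.defined]


def _event_densities(e: MovementEvent, include_focal: bool):
    """Per-feeder density vectors for both windows plus the leave/arrive
    densities of one event.

    With ``include_focal`` the focal is added back at its origin feeder in
    both windows (during the arrival window it is in transit and its last
    known feeder is the origin)."""
    m_dep = e.occupancy_at_departure.counts_total.astype(float)
    m_arr = e.occupancy_at_arrival.counts_total.astype(float)
    if include_focal:
        f = e.from_feeder - 1
        n_dep = m_dep.copy(); n_dep[f] += 1
        n_arr = m_arr.copy(); n_arr[f] += 1
        rho_dep = n_dep / n_dep.sum()
        rho_arr = n_arr / n_arr.sum()
    else:
        rho_dep = m_dep / m_dep.sum()
        rho_arr = m_arr / m_arr.sum()
    return rho_dep, rho_arr, rho_dep[e.from_feeder - 1], rho_arr[e.to_feeder - 1]


def _curve_arrays(events: Sequence[MovementEvent], bin_edges: np.ndarray,
                  prior: float, pooled: bool, include_focal: bool) -> tuple:
    dens = [_event_densities(e, include_focal) for e in events]
    rho_leave = np.array([d[2] for d in dens])
    rho_arrive = np.array([d[3] for d in dens])
    dep_all = np.concatenate([d[0] for d in dens])
    arr_all = np.concatenate([d[1] for d in dens])

    h_leave = np.histogram(rho_leave, bin_edges)[0]
    h_arrive = np.histogram(rho_arrive, bin_edges)[0]

    if pooled:
        ref = np.concatenate([dep_all, arr_all])
        p_ref_l = p_ref_a = np.histogram(ref, bin_edges)[0] / len(ref)
    else:
        p_ref_l = np.histogram(dep_all, bin_edges)[0] / len(dep_all)
        p_ref_a = np.histogram(arr_all, bin_edges)[0] / len(arr_all)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_leave = np.where(p_ref_l > 0,
                           (h_leave / len(events)) * prior / p_ref_l, np.nan)
        p_arrive = np.where(p_ref_a > 0,
                            (h_arrive / len(events)) * prior / p_ref_a, np.nan)
    return p_leave, p_arrive, h_leave, h_arrive, p_ref_l, p_ref_a


def empirical_density_curves(events: Sequence[MovementEvent],
                             bin_edges: np.ndarray | None = None,
                             prior: float = PRIOR_ARRIVAL,
                             pooled: bool = True,
                             include_focal: bool = True) -> DensityCurve:
    """Bayes-rule estimates of P(leave | rho) and P(arrive | rho).

    The reference density distribution P(rho) pools every feeder of both
    occupancy windows across all usable events (``pooled=False`` keeps the
    departure-window and arrival-window references separate).  With
    ``include_focal=False`` events with an empty patch (undefined rho) are
    excluded.
    """
    events = _usable(events, include_focal)
    if not events:
        raise ValueError("no usable events (all have undefined occupancy)")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    p_leave, p_arrive, h_l, h_a, _, _ = _curve_arrays(events, bin_edges, prior,
                                                      pooled, include_focal)
    return DensityCurve(bin_edges=bin_edges, p_leave=p_leave, p_arrive=p_arrive,
                        n_leave=h_l, n_arrive=h_a, prior_arrival=prior)


def jackknife_envelope(events: Sequence[MovementEvent],
                       bin_edges: np.ndarray | None = None,
                       reps: int = 1000, frac_removed: float = 0.4,
                       seed: int = 0, prior: float = PRIOR_ARRIVAL,
                       pooled: bool = True, include_focal: bool = True) -> dict:
    """Delete-d jackknife min-max envelope of the empirical curves.

    Each replicate removes round(frac_removed * n) events uniformly at
    random and recomputes both curves; the envelope is the per-bin minimum
    and maximum across replicates (the maximal variability range).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (0 <= frac_removed < 1):
        raise ValueError("frac_removed must be in [0, 1)")
    events = _usable(events, include_focal)
    if not events:
        raise ValueError("no usable events")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(events)
    d = int(round(frac_removed * n))
    lo_l = np.full(len(bin_edges) - 1, np.inf)
    hi_l = np.full(len(bin_edges) - 1, -np.inf)
    lo_a, hi_a = lo_l.copy(), hi_l.copy()
    for _ in range(reps):
        keep_idx = rng.permutation(n)[: n - d] if d else np.arange(n)
        sub = [events[i] for i in keep_idx]
        pl, pa, *_ = _curve_arrays(sub, bin_edges, prior, pooled, include_focal)
        lo_l, hi_l = np.fmin(lo_l, pl), np.fmax(hi_l, pl)
        lo_a, hi_a = np.fmin(lo_a, pa), np.fmax(hi_a, pa)
    def _clean(x):
        return np.where(np.isfinite(x), x, np.nan)
    return {"leave_low": _clean(lo_l), "leave_high": _clean(hi_l),
            "arrive_low": _clean(lo_a), "arrive_high": _clean(hi_a),
            "reps": reps, "frac_removed": frac_removed, "seed": seed}


def tasp_curves(density_grid: np.ndarray,
                arrival_form: str = "inverse") -> DensityCurve:
    """Theoretical asocial prediction on a density grid.

    Leaving: P(L | rho) = rho (a uniformly chosen mover is at a feeder with
    probability equal to its density; a feeder holding the whole patch is
    left with probability 1).  Arrival: P(A | rho) = (1 - rho) / 3 under the
    default "inverse" reading (the mover is elsewhere with probability
    1 - rho and picks uniformly among three alternative feeders);
    ``arrival_form="literal"`` selects the proportional form 0.33 * rho
    instead.
    """
    rho = np.asarray(density_grid, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("density grid must lie in [0, 1]")
    p_leave = rho.copy()
    if arrival_form == "inverse":
        p_arrive = (1.0 - rho) / 3.0
    elif arrival_form == "literal":
        p_arrive = 0.33 * rho
    else:
        raise ValueError("arrival_form must be 'inverse' or 'literal'")
    edges = np.concatenate([rho, [np.nan]])  # grid, not bins; edges unused
    zeros = np.zeros_like(rho, dtype=int)
    return DensityCurve(bin_edges=edges, p_leave=p_leave, p_arrive=p_arrive,
                        n_leave=zeros, n_arrive=zeros)


def tasp_on_bins(bin_edges: np.ndarray, arrival_form: str = "inverse") -> DensityCurve:
    """TASP evaluated at the midpoints of a set of rho bins."""
    edges = np.asarray(bin_edges, dtype=float)
    mid = np.clip(0.5 * (edges[:-1] + edges[1:]), 0.0, 1.0)
    curve = tasp_curves(mid, arrival_form=arrival_form)
    curve.bin_edges = edges
    return curve


def tasp_expected_on_bins(events: Sequence[MovementEvent],
                          bin_edges: np.ndarray | None = None,
                          include_focal: bool = True) -> DensityCurve:
    """TASP prediction for a given binning of a given event set.

    Densities are discrete (counts over small flocks), so within a rho bin
    the attainable densities need not centre on the bin midpoint; the
    binned Bayes-rule estimate converges to the slot-frequency-weighted
    mean of the TASP over the densities actually observed in the bin.  This
    evaluates that expectation — P(L|bin) = mean slot rho in the bin,
    P(A|bin) = (1 - mean slot rho)/3 — giving the exact null to compare a
    binned empirical curve against.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    events = _usable(events, include_focal)
    dens = [_event_densities(e, include_focal) for e in events]
    slots = np.concatenate([np.concatenate([d[0], d[1]]) for d in dens])
    idx = np.digitize(slots, bin_edges) - 1
    n_bins = len(bin_edges) - 1
    mean_rho = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            mean_rho[b] = slots[sel].mean()
    return DensityCurve(bin_edges=bin_edges, p_leave=mean_rho,
                        p_arrive=(1 - mean_rho) / 3.0,
                        n_leave=counts, n_arrive=counts)


def curve_standard_errors(events: Sequence[MovementEvent],
                          bin_edges: np.ndarray | None = None,
                          prior: float = PRIOR_ARRIVAL,
                          pooled: bool = True,
                          include_focal: bool = True) -> dict:
    """Delta-method standard errors of the Bayes-rule curve estimates.

    The estimate in each bin is prior * (a/n_A) / (b/n_ref) with a and b
    binomial counts; the SE follows from the variance of the log ratio,
    var ~ 1/a - 1/n_A + 1/b - 1/n_ref.  Bins with no events get NaN.
    """
    events = _usable(events, include_focal)
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    pl, pa, h_l, h_a, p_ref_l, p_ref_a = _curve_arrays(events, bin_edges, prior,
                                                       pooled, include_focal)
    n_ev = len(events)
    n_ref = (8 if pooled else 4) * n_ev
    with np.errstate(divide="ignore", invalid="ignore"):
        b_l = p_ref_l * n_ref
        b_a = p_ref_a * n_ref
        var_log_l = 1 / h_l - 1 / n_ev + 1 / b_l - 1 / n_ref
        var_log_a = 1 / h_a - 1 / n_ev + 1 / b_a - 1 / n_ref
        se_l = np.abs(pl) * np.sqrt(np.maximum(var_log_l, 0))
        se_a = np.abs(pa) * np.sqrt(np.maximum(var_log_a, 0))
    se_l = np.where(h_l > 0, se_l, np.nan)
    se_a = np.where(h_a > 0, se_a, np.nan)
    return {"leave": se_l, "arrive": se_a}
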