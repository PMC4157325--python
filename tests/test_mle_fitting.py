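"""Tests for likelihood evaluation, maximum-likelihood fitting and
profile-likelihood confidence intervals."""

import math

import numpy as np
import pytest

from conftest import make_event
from flockdecide.decision_model import ModelParams, choice_probabilities
from flockdecide.mle_fitting import (event_log_likelihood, total_log_likelihood,
                                     null_log_likelihood, fit, profile_ci)
from flockdecide.synthetic_data import SyntheticConfig, simulate_decision_events


def social_events(n=400, seed=0, params=None, species="great_tit"):
    params = params or ModelParams(s_c=6.0, s_h=2.0, k=0.02, a=5.0)
    return simulate_decision_events(params, species, n,
                                    SyntheticConfig(seed=seed), seed=seed + 1)


class TestEventLogLikelihood:
    def test_asocial_gives_log_one_third_conditional(self):
        e = make_event([4, 1, 0, 2], [1, 0, 3, 0], from_feeder=1, to_feeder=3)
        ll = event_log_likelihood(ModelParams(s=1.0, a=7.0), e)
        assert ll == pytest.approx(math.log(1 / 3), abs=1e-12)
        ll4 = event_log_likelihood(ModelParams(s=1.0, a=7.0), e,
                                   convention="unconditional")
        assert ll4 == pytest.approx(math.log(1 / 4), abs=1e-12)

    def test_certainty_limit_for_strong_attraction(self):
        e = make_event([0, 0, 9, 0], [0, 0, 6, 0], from_feeder=1, to_feeder=3)
        # k > 0 makes the crowded destination discount the empty options
        ll = event_log_likelihood(ModelParams(s=200.0, k=0.5, a=1.0), e)
        assert -1e-6 < ll <= 0

    def test_total_equals_brute_force_product(self):
        events = social_events(n=5, seed=3)
        params = ModelParams(s_c=3.0, s_h=1.5, k=0.1, a=2.0)
        brute = 1.0
        for e in events:
            occ = e.occupancy_at_arrival
            p = choice_probabilities(params, occ.counts_conspecific,
                                     occ.counts_heterospecific).probabilities
            keep = p.sum() - p[e.from_feeder - 1]
            brute *= p[e.to_feeder - 1] / keep
        assert total_log_likelihood(params, events) == pytest.approx(
            math.log(brute), rel=1e-10)


class TestFit:
    def test_recovers_asocial_rate(self):
        events = simulate_decision_events(ModelParams(s=1.0), "great_tit", 2000,
                                          SyntheticConfig(seed=10), seed=11)
        res = fit(events, variant="single-s")
        assert 0.8 <= res.params.s <= 1.25
        assert res.converged

    def test_duplicated_events_same_estimate_double_loglik(self):
        events = social_events(n=300, seed=4)
        res1 = fit(events, variant="two-s")
        res2 = fit(events + events, variant="two-s")
        assert res2.params.s_c == pytest.approx(res1.params.s_c, rel=1e-4)
        assert res2.params.a == pytest.approx(res1.params.a, rel=1e-4)
        assert res2.log_likelihood == pytest.approx(2 * res1.log_likelihood, rel=1e-8)

    def test_order_invariance(self):
        events = social_events(n=200, seed=5)
        res1 = fit(events, variant="two-s")
        res2 = fit(list(reversed(events)), variant="two-s")
        # summation order changes floating-point rounding, nothing more
        assert res2.params.s_c == pytest.approx(res1.params.s_c, rel=1e-2)
        assert res2.params.s_h == pytest.approx(res1.params.s_h, rel=1e-2)
        assert res2.params.a == pytest.approx(res1.params.a, rel=1e-2)

    def test_fitted_loglik_dominates_asocial_null(self):
        for seed, params in ((6, ModelParams(s=1.0)),
                             (7, ModelParams(s_c=6.0, s_h=2.0, k=0.02, a=5.0))):
            events = simulate_decision_events(params, "great_tit", 300,
                                              SyntheticConfig(seed=seed), seed=seed)
            res = fit(events, variant="two-s")
            assert res.log_likelihood >= null_log_likelihood(res.n_events) - 1e-6

    def test_species_filter_restricts_events(self):
        events = (social_events(n=100, seed=8, species="great_tit")
                  + social_events(n=50, seed=9, species="blue_tit"))
        res = fit(events, variant="two-s", species_filter="blue_tit")
        assert res.n_events == 50
        assert res.species_filter == "blue_tit"

    def test_small_sample_warns(self):
        events = social_events(n=5, seed=12)
        with pytest.warns(UserWarning, match="unstable"):
            fit(events, variant="single-s")

    def test_two_s_recovery_within_field_uncertainty(self):
        # generate at the published great-tit rule and refit: estimates land
        # inside that study's 95% ranges (its own uncertainty at this n)
        truth = ModelParams(s_c=12.64, s_h=2.10, k=0.01, a=13.48)
        events = simulate_decision_events(truth, "great_tit", 2259,
                                          SyntheticConfig(seed=77), seed=78)
        res = fit(events, variant="two-s")
        assert 5.05 <= res.params.s_c <= 21.98
        assert 7.38 <= res.params.a <= 24.43


class TestProfileCI:
    def test_interval_contains_estimate_and_truth(self):
        events = social_events(n=800, seed=20,
                               params=ModelParams(s_c=4.0, s_h=2.0, k=0.0, a=3.0))
        res = fit(events, variant="two-s")
        lo, hi, flags = profile_ci(events, res, "s_c")
        assert lo <= res.params.s_c <= hi
        assert lo <= 4.0 <= hi

    def test_wald_limit_of_quadratic_profile(self):
        # at large n the profile is near-quadratic in log s and the profile
        # interval approaches estimate +/- 1.96 SE
        events = simulate_decision_events(ModelParams(s=2.0, k=0.5, a=1.0),
                                          "great_tit", 1500,
                                          SyntheticConfig(seed=21), seed=22)
        res = fit(events, variant="single-s")
        lo, hi, _ = profile_ci(events, res, "s")
        ls, llo, lhi = np.log([res.params.s, lo, hi])
        # numerical curvature of the profile in log s
        from flockdecide.mle_fitting import _design, _nll, _pack
        nc, nh, to, frm = _design(events, "arrival")
        h = 0.05
        th = _pack(res.params)
        def prof(x):
            t = th.copy(); t[0] = x
            from scipy.optimize import minimize
            r = minimize(lambda f: _nll(np.array([x, f[0], f[1]]), "single-s",
                                        nc, nh, to, frm, "conditional"),
                         th[1:], method="L-BFGS-B",
                         bounds=[(0, 5), (-3, 6)])
            return r.fun
        curv = (prof(ls + h) - 2 * prof(ls) + prof(ls - h)) / h ** 2
        se = 1 / math.sqrt(curv)
        assert llo == pytest.approx(ls - 1.96 * se, abs=0.4 * se)
        assert lhi == pytest.approx(ls + 1.96 * se, abs=0.4 * se)

    def test_k_lower_bound_is_flagged(self):
        events = social_events(n=600, seed=26,
                               params=ModelParams(s_c=6.0, s_h=2.0, k=0.0, a=5.0))
        res = fit(events, variant="two-s")
        assert res.params.k == 0.0  # estimate pinned at the boundary
        lo, hi, flags = profile_ci(events, res, "k")
        assert lo == 0.0
        assert flags["lower_at_bound"]

    def test_coverage_of_generating_value(self):
        # profile intervals should cover the generating s in most replicates
        hits = 0
        for i in range(8):
            events = simulate_decision_events(ModelParams(s=2.5, k=0.0, a=2.0),
                                              "great_tit", 400,
                                              SyntheticConfig(seed=30 + i),
                                              seed=60 + i)
            res = fit(events, variant="single-s")
            lo, hi, _ = profile_ci(events, res, "s")
            hits += lo <= 2.5 <= hi
        assert hits >= 6
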