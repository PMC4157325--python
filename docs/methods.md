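# Methods

`flockdecide` implements a complete analysis chain for collective
decision-making in mixed-species songbird flocks foraging at an
instrumented patch of four identical feeders: event extraction from
PIT-tag detection streams, density-conditioned movement probabilities with
an asocial null, maximum-likelihood fitting of a social decision rule, and
an agent-based replay of the fitted rule. This note records the models,
the conventions adopted where the design was genuinely open, and the
limits of what the synthetic-data tests demonstrate.

## Detection streams and movement events

The raw data unit is a detection: one record per tagged bird per feeder
per 15 s logging interval. A *movement event* is a pair of consecutive
detections of the same bird at two different feeders separated by at most
a gap threshold, 240 s by default — the point at which the inter-detection
gap distribution turns from the within-visit peak into the between-visit
tail, so longer gaps are read as leaving and re-entering the patch rather
than moving within it. `estimate_gap_threshold` offers a data-driven
stand-in for that constant: a two-component exponential mixture is fitted
to the positive gaps by EM (deterministic median-split initialisation) and
the threshold is the gap at which the component responsibilities cross
0.5, rounded to the logging interval. The mixture is a heuristic for a
changepoint that field workers usually place by eye; the 240 s default is
retained whenever fewer than 50 gaps are available or the mixture
degenerates.

Each event carries the occupancy of all four feeders in the half-open
window `[t − 30 s, t)` before departure and before arrival (two logging
intervals). Within a window each bird is assigned to the feeder of its
most recent detection, ties breaking to the lower-numbered feeder, so no
bird is double-counted. The focal bird is removed from its own occupancy
vectors: its presence must not count as social information in its own
decision. Events whose windows contain no other bird are retained but
flagged; their relative densities are undefined and the likelihood stage
skips them. Two conventions are fixed where the data admit ambiguity: a
bird read at two feeders within one logging interval is treated as having
moved, with the lower-numbered feeder as origin; and the "day 1" filter
used for robustness checks starts at the patch's first detection, not at
civil midnight.

## Density curves and the theoretical asocial prediction

For the population-level description, Bayes' rule converts observed feeder
densities ρ (a feeder's share of the birds in the patch) into movement
probabilities:

    P(A | ρ) = P(ρ | A) · P(A) / P(ρ),

with the arrival prior fixed at P(A) = 1/4 because the feeders are
identical, P(ρ | A) estimated from arrival-feeder densities at events,
P(ρ | L) from origin-feeder densities, and the reference P(ρ) pooled over
every feeder of both event windows (a switch keeps the two windows'
references separate). Densities are binned into 11 equal-width bins
centred on 0.0–1.0; empty reference bins are reported as undefined (NaN),
never as zero, and bins with fewer than five events should be read with
their printed sample sizes in mind — no smoothing is applied.

The null model is the *theoretical asocial prediction* (TASP): a mover
chosen uniformly at random sits at a feeder with probability equal to that
feeder's density, so P(L | ρ) = ρ, and relocates uniformly among the three
other feeders, so P(A | ρ) = (1 − ρ)/3. This null is exact at the
boundaries (a feeder holding the whole patch is left with probability 1)
and distinguishes "pick a random bird" from the naive "pick a random
feeder" null, which would put both probabilities at constants.

One estimator convention deserves emphasis. The TASP places the mover at
a feeder with probability equal to the *including-mover* density, whereas
the stored occupancy vectors exclude the focal. Conditioning the curves
on others-only densities would make the asocial curves provably flat at
the prior — when birds sit independently of one another, the
configuration of the others says nothing about where the mover is — and
no estimator built on them can reproduce TASP. The curve estimator
therefore adds the focal back at its origin feeder when computing
densities (origin density (m_i + 1)/(M + 1), arrival density
m_j/(M + 1), reference slots from the full configuration). Under this
convention the estimator recovers TASP exactly for movement data generated
by the asocial rule, for any distribution of flock configurations; the
focal-removed vectors remain exactly what the decision-model likelihood
consumes. `include_focal=False` switches to the literal others-only
estimator for comparison.

Because densities are discrete (counts over flocks of ten or twenty
birds), the attainable ρ values inside a bin rarely centre on the bin
midpoint. `tasp_expected_on_bins` evaluates the null as the
slot-frequency-weighted mean of the TASP over the densities actually
observed in each bin; that, not the midpoint value, is the correct
benchmark for a binned empirical curve, and the distinction matters at
exactly the precision the Monte-Carlo equivalence checks run at.

Uncertainty on the empirical curves is a delete-d jackknife envelope:
`reps` subsamples (default 1000) each drop a fixed fraction of events
(default 40%), and the envelope is the per-bin minimum and maximum of the
recomputed curves — a maximal variability range, deliberately not a
percentile interval.

## The decision rule

A bird choosing among feeders scores each feeder x by

    P(X_x | B) = 1 / (1 + a · s^−(n_x − k Σ_{i≠x} n_i))

where `s` is the rate of social information use (an individual's judgement
that others make a good choice s times more often than a bad one), `k`
weighs how much occupancy elsewhere discounts a feeder's estimated
quality (k → 1: relative comparison; k → 0: absolute counts), and `a` is
the quality of nonsocial information (a > 1 penalises empty feeders; the
feeders being identical, a single `a` is shared by all four). The
two-class variant splits the social term into conspecific and
heterospecific factors with rates `s_c` and `s_h` and reduces exactly to
the single-rate rule when s_c = s_h. Because the scores need not sum to
one, probability matching divides each score by the sum of the four; the
resulting choice probabilities are strictly positive — an empty feeder is
never impossible — and collapse to exactly 1/4 each when s = 1, whatever
the occupancy. Exponents use raw counts, not densities, and scores are
computed in log space (`log_expit`), so large rates and counts cannot
overflow.

Choice surfaces plot P(choose x) over all combinations of conspecifics
and heterospecifics at x for fixed patch totals, with birds not at x
split as evenly as integer counts allow across the other three feeders
(earlier feeders take the remainder; the convention is recorded in every
surface output). The P = 1/4 contour marks the threshold above which a
site is chosen more often than at random; `threshold_count` reads that
threshold along one class axis with the other class absent from x. Under
the reference great-tit rule the conspecific threshold is 3 birds of 10 —
thresholds scale with flock size in proportion rather than as absolute
counts.

## Likelihood and fitting

Each observed movement is scored by the probability the rule assigns to
the destination actually chosen, computed from the arrival-window
occupancy (the information available at the moment the destination is
chosen; the departure-window context is available as an option). The
default *conditional* convention renormalises the four-way choice
distribution over the three feeders other than the origin, conditioning
on the fact that a move was observed; the *unconditional* alternative
scores the destination under the full four-way distribution including
staying. Both are first-class because the event-ascertainment process
(only feeder changes are observable as events) does not dictate a unique
joint form for "a departure and an arrival"; the convention used is
recorded in every fit result.

Fitting maximises the summed log-likelihood over (log s or
log s_c/log s_h, k, log a) by L-BFGS-B with box bounds
s, a ∈ [e⁻³, e⁶] and k ∈ [0, 5] — positivity plus generous head-room
around empirically plausible magnitudes. The fit is deterministic given
the data and start; on non-convergence five dispersed starts are tried
and the best likelihood kept. The s = 1 rule is nested in every variant,
so the fitted log-likelihood can never fall below n·log(1/3) (conditional
convention); this nesting is asserted in the tests. Confidence intervals
are profile-likelihood intervals at 95%: the set of parameter values
whose log-likelihood, re-optimising all other parameters, lies within
χ²₁(0.95)/2 ≈ 1.92 of the maximum. Endpoints are found by outward
geometric expansion then bisection (tolerance 10⁻³ on the transformed
scale), warm-starting each re-optimisation; an endpoint clipped at a
parameter bound is flagged (`k = 0` being the common case), as is a flat
profile.

## Agent-based simulation

The replay experiment draws a flock snapshot per simulated flock and runs
50 decisions (1000 flocks by default): one bird selected uniformly at
random, its four-way choice distribution computed from the rule with its
own presence removed from the counts (staying = choosing its current
feeder), the destination sampled, the flock updated. Feeder changes are
emitted as movement events with synthetic timestamps at one decision per
logging interval, and the downstream curve estimation runs on the
identical code path as for detection-derived events. In mixed flocks each
mover follows its own species' fitted rule by default, with a single-rule
override. Bird count is conserved within a flock; there are no
simultaneous movers and no mid-run arrivals or departures.

## Synthetic data generator

No field data accompany this package, so the generator emulates the
structure of the winter feeder data the pipeline is designed for: five
species with strongly skewed abundances (visit shares 34.3 / 32.5 / 16.4 /
11.2 / 6.0% for blue tit, great tit, marsh tit, coal tit, nuthatch; a
tagged pool of 1904 birds), four feeders, one record per bird per feeder
per 15 s interval, and bursty flock visits with free entry and exit.
Where the field system fixes no law, defaults were chosen once on
realism grounds and are all configurable: flock visits arrive as a
homogeneous Poisson process (6 visits/h); flock sizes are negative
binomial (mean 15, shape 2 — winter tit flocks of a few to a few tens of
birds, overdispersed); arriving birds pick feeders sequentially with the
generator's own decision rule, and species sub-flocks clump
semi-independently (per-species Dirichlet-multinomial allocation with
concentration 0.8) in the parametric snapshot sampler; each present bird
re-evaluates its feeder every interval with probability 0.3 and leaves
the patch with hazard 0.05 per interval (mean visit five minutes).
Detection is complete: a bird is logged in every interval it is present
(tag coverage in the emulated system exceeded 90%, and detection failure
is deliberately not modelled).

`simulate_decision_events` is the parameter-recovery workhorse: it draws
an independent snapshot per decision, picks a focal of the requested
species, samples its choice under a known rule, and keeps the feeder
changes — exactly the data-generating process the conditional likelihood
assumes, so refitting closes the loop.

What passing these tests shows — and does not. Recovery tests demonstrate
that the extraction, likelihood and optimiser are mutually consistent and
that the rule's parameters are identifiable at realistic sample sizes
(2259 movements, the scale of the field dataset). They cannot show that
real birds follow the rule: the generator has no spatial geometry beyond
feeder identity, no dominance, depletion, predation or detection failure,
and its flock-size and arrival laws are stand-ins. Conclusions about real
flocks rest on fitting real streams, for which this package supplies the
machinery, not the evidence.

## Problem sizes and numerical choices

Equivalence of the asocial simulation with TASP is checked at the full
replay size (1000 flocks × 50 decisions) against three delta-method
standard errors per bin, ignoring bins with fewer than ten events.
Parameter recovery uses 20 replicates of 2259 movements per species set
and reports medians, which are robust to the occasional poorly
conditioned fit; unit and property tests use hundreds of events, enough
for the properties they assert. Probability sums are checked to 1e-12;
curve bins with undefined estimates propagate NaN rather than zero;
jackknife subsampling, snapshot draws and all simulations are driven by
explicit integer seeds, and every pipeline stage derives its seed from
one master seed by fixed offsets, making full runs byte-reproducible.

## Known limitations

- The conditional likelihood scores arrivals only; if the true
  data-generating process couples departure timing to occupancy, those
  terms are ignored (the unconditional convention is a partial
  sensitivity check).
- The profile-CI search assumes a unimodal profile; multimodal
  likelihoods would need a grid scan.
- The gap-threshold mixture assumes exponential components; heavy-tailed
  between-visit gaps bias the crossing downwards.
- Occupancy windows shorter than a bird's true decision horizon
  undercount the flock; the 30 s default follows the two-interval
  convention of the emulated hardware.
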