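# flockdecide

Collective decision-making analysis of mixed-species songbird flocks at
automated feeder patches.

Wintering woodland passerines (blue tits, great tits, marsh tits, coal
tits, nuthatches) forage in mixed-species flocks. When such a flock works
a patch of four identical seed feeders, every bird repeatedly decides
whether to stay at its feeder or relocate — and those decisions can be
read, bird by bird, from PIT-tag detections logged by antennae on the
feeders. `flockdecide` turns such detection streams into quantitative
statements about the social rules behind flock cohesion:

1. **Movement extraction** — merge per-feeder streams, find every
   within-patch movement (consecutive detections at two feeders no more
   than 240 s apart), and attach the occupancy of all four feeders in the
   30 s before departure and arrival, with the focal bird removed from its
   own context.
2. **Density curves** — estimate P(leave | ρ) and P(arrive | ρ) by Bayes'
   rule, `P(A|ρ) = P(ρ|A)·P(A)/P(ρ)` with prior P(A) = 1/4, where ρ is a
   feeder's share of the birds in the patch; uncertainty comes from a
   delete-d jackknife envelope (1000 replicates, 40% of events removed).
3. **Asocial null (TASP)** — the theoretical asocial prediction for a
   uniformly chosen mover: P(leave | ρ) = ρ and P(arrive | ρ) = (1 − ρ)/3.
   Departures from it measure social attraction or repulsion.
4. **Decision-model fitting** — maximum-likelihood estimation of the
   sigmoidal social choice rule

       P(X_x | B) = 1 / (1 + a · s_c^−(nc_x − k Σ nc_i) · s_h^−(nh_x − k Σ nh_i))

   followed by probability matching (scores divided by their sum).
   `s_c` and `s_h` are conspecific and heterospecific rates of social
   information use (s = 1: no social response), `k` weighs occupancy at
   other feeders, `a` the quality of nonsocial information. Profile
   likelihood gives 95% confidence intervals.
5. **Agent-based replay** — simulate flocks (default 1000 flocks × 50
   decisions) under a fitted rule, with each mover's four-way choice
   (staying included) computed from the occupancy minus itself, and push
   the simulated movements through the identical curve estimation for a
   model-versus-data comparison.

A synthetic-data module generates detection streams with the structure of
the field system (skewed five-species community, bursty flock visits, one
record per bird per feeder per 15 s interval), so the whole pipeline is
testable end to end — including recovering known generating parameters.

## Worked example

```python
import flockdecide as fd
from flockdecide.synthetic_data import SyntheticConfig, generate_dataset
from flockdecide.decision_model import GREAT_TIT_FIT

cfg = SyntheticConfig(seed=7, session_length=2 * 3600.0, n_individuals=600,
                      flock_arrival_rate=8.0, generator_params=GREAT_TIT_FIT)
stream = generate_dataset(cfg)          # 2830 detections by 131 birds
events = fd.extract_movements(stream)   # 470 within-patch movements

curve = fd.empirical_density_curves(events)
res = fd.fit(events, variant="two-s", species_filter="great_tit")
```

The two-hour synthetic session above, generated under a social rule,
yields 2830 detections, 470 movements, and the binned curves

```
bin_mid:   0.0   0.1   0.2   0.3   0.4   0.5   0.6   0.7   0.8   0.9   1.0
p_leave:  0.005 0.180 0.226 0.356 0.342 0.521 0.508 0.538 0.727 0.667 1.026
p_arrive: 0.123 0.125 0.302 0.379 0.396 0.339 0.455 0.276 0.182 0.533 0.0
```

Compared with the asocial null (leave = ρ, arrive = (1 − ρ)/3) the birds
over-leave sparse feeders and over-arrive at busy ones — the signature of
social attraction. The fit to the 159 great-tit decisions prints

```
s_c = 5.15, s_h = 1.58, k = 0.10, a = 3.88, logL = -125.3
```

conspecific attraction (s_c) clearly above heterospecific (s_h), as in the
generating rule; at a few hundred events the estimates are noisy, which is
what the profile intervals are for.

The package also installs a CLI wrapping the same functions:

```
flockdecide generate --seed 7 --out stream.csv
flockdecide extract stream.csv --out events.csv
flockdecide curves events.csv --out curves.csv
flockdecide fit events.csv --species great_tit --out fit.json
flockdecide simulate --params-json fit.json --stream-csv stream.csv
flockdecide run config.yaml          # full pipeline + manifest
```

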