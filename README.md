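# pairforage

Analysis of **within-pair coordination of parental care in central-place
foragers**, from simultaneous GPS tracks of both pair members.

In many seabirds both parents alternate long foraging trips with nest
bouts, and a parent about to leave cannot see what its partner is doing
at sea. Whether partners nevertheless coordinate — staying at the nest
until the other returns, matching each other's effort trip by trip, or
converging on similar overall investment — is a central question in the
study of biparental care. `pairforage` implements the full analysis
chain for dual-GPS data from chick-rearing pairs (the motivating system
is the lesser black-backed gull, *Larus fuscus*, tracked at 3-minute
fixes over the 30-day chick-rearing window):

1. **Segmentation** (`trackdata`): each track is spliced into foraging
   trips — from the last fix inside the colony boundary to the first
   fix back inside — and complementary nest bouts; trips shorter than
   30 min or covering less than 1 km are discarded as non-foraging.
2. **Temporal coordination** (`coordination`): for each pair, four
   statistics — the proportion of male (female, pooled) departures with
   the partner inside the colony, and nest attendance (fraction of time
   with ≥1 parent present) — are tested one-tailed against a
   randomisation null that permutes each bird's trip-duration and
   bout-duration multisets (999 rebuilds, alternation preserved). The
   observed statistic is compared with the null as
   p = (1 + #{null ≥ observed}) / (R + 1); small schedules are
   enumerated exhaustively instead of sampled.
3. **Behavioural annotation** (`annotate`): a random-forest classifier
   of rest / commute / forage from path geometry (step length, signed
   turning angle), habitat and body movement (ground speed,
   accelerometer class), selected among 12 candidate input structures
   (4 stream sets × windows of 1/3/5 points) with an
   individual-level train/validation split.
4. **Co-adjustment models** (`models`): gamma GLMs with log link for
   focal trip duration vs. the partner's preceding trip duration
   (× sex), and nest-bout duration vs. offspring age (× sex).
5. **Within-pair similarity** (`similarity`): a from-scratch Multiple
   Response Permutation Procedure (MRPP) on per-trip investment
   parameters (distance, duration, resting/flying/foraging hours),
   per colony, with delta = Σ (n_g/N) · (mean within-pair dissimilarity)
   and a 999-permutation, one-tailed-low null.
6. **Synthetic paired tracks** (`simulate`): a generator of paired
   schedules and movement with *known* coordination strength —
   departure gating with probability `w` (a bird waits for its partner
   before leaving) — plus behaviour-dependent kinematics, confusion-
   matrix accelerometer classes and a land-cover patch map, so every
   stage is testable without field data.

## Worked example

Simulate one pair under the default study-scale conditions (30 days,
3-min fixes, gamma trips with mean 4.4 h, coordination `w = 0.6`) and
test its coordination:

```python
import numpy as np
from pairforage import (SimConfig, simulate_pair_schedule, PairSchedule,
                        compute_stats, randomisation_test)

cfg = SimConfig(seed=1)
pair = PairSchedule.from_simulation(simulate_pair_schedule(cfg, "P001"),
                                    cfg.window_h)
obs = compute_stats(pair)
res = randomisation_test(pair, n_rep=999, rng=np.random.default_rng(1))
```

This prints (via the fields of `obs` and `res`):

```
trips: male 60, female 59
observed partner presence: 0.689
expected under null:       0.467
difference:                0.222
one-tailed p:              0.001
nest attendance:           0.826 (p = 0.001)
```

The pair departs with its partner present far more often (0.689) than
the 0.467 expected if the two schedules were independent, and the
randomisation test flags the coordination at p ≈ 0.001 — the signature
of turn-taking produced here, by construction, through departure
gating.

The same chain runs from the shell:

```bash
pairforage simulate --seed 1 --n-pairs 25 --out sim/
pairforage segment --fixes sim/fixes.csv --colony colony.json --out seg/
pairforage run --config run.yaml --out results/
```

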