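# pairforage

Do breeding partners of a central-place foraging seabird forage alike, or do
they complement each other?  `pairforage` is a tested Python pipeline for
answering that question from biologging deployments on both members of known
breeding pairs: GPS tracks and time–depth records go in; activity budgets,
foraging-trip and dive metrics, kernel space-use overlap, and a
real-vs-randomized-pair inference come out.  A synthetic colony generator
with configurable pairing structure makes every stage verifiable by
parameter recovery, so the package is usable (and fully testable) without
any field data.

It is written for movement ecologists working on species like auks,
penguins and shearwaters, where both mates provision the chick from a
common colony and the interesting contrast is each female crossed with
every male tracked in the same season.

## The analysis

1. **Regularize** GPS fixes to a 5-min step series (great-circle
   interpolation, long gaps flagged).
2. **Classify** each step into *colony / diving / flying / swimming* with a
   4-state hidden Markov model (step length ~ Gamma, flight intensity ~
   Normal, dive indicator ~ Bernoulli), fitted by Baum–Welch and decoded by
   Viterbi, with a 1-km splashdown override near the colony.
3. **Segment** dives (depth ≥ 1 m for ≥ 3 s) and foraging trips
   (> 1 km from the colony, > 20 min, ≥ 1 dive) and compute the deployment
   metric set, including *differential depth* (a dive's depth minus the
   hourly population mean, removing the diel cycle).
4. **Space use**: per-bird kernel utilization distributions on a 200-m
   metric grid (common bandwidth = mean per-bird h_ref, 2720 m in the
   reference configuration), 50%/95% volume contours, and Bhattacharyya's
   Affinity BA = Σ√(p_F·p_M) between the core areas of every female × male
   combination.
5. **Pairing inference**: the pair table crosses every female with every
   male per season (19×19 + 21×21 = 802 rows at the default design, 40 real
   pairs), with |female − male| per trait.  The probability of being a real
   pair is fitted by weighted logistic regression (IRLS) with AICc model
   selection; a matching-permutation test (random perfect matchings of
   females to males within year) provides an exact null that respects each
   bird appearing in exactly one real pair.  A **positive** slope on a |Δ|
   covariate means real mates are *more different* than chance
   (disassortative); a **negative** slope means they are more similar.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate the default two-season colony (19 + 21 pairs, 72-h deployments,
disassortative trip distance and dive rate, assortative wing length) and run
the full chain:

```python
from pairforage import PipelineConfig, run_pipeline

cfg = PipelineConfig(output_dir="murre_run", n_perm=999, seed=1)
bundle = run_pipeline(cfg)

pairs = bundle["pairs"]
print(f"pair table: {pairs['n_rows']} rows, {pairs['n_real']} real pairs")
for group, res in pairs["groups"].items():
    print(f"[{group}] best model: {res['best_model']}")
coef = pairs["groups"]["foraging"]["best_coef"]
print(f"trip-distance slope: {coef['mean_trip_distance_km']:+.3f}")
for trait, res in pairs["permutation_tests"].items():
    print(f"permutation {trait}: T={res['statistic']:+.3f}  p={res['p']:.4f}")
```

which prints (about a minute on one CPU):

```
pair table: 802 rows, 40 real pairs
[foraging] best model: ~ mean_trip_distance_km
[diving] best model: ~ dives_per_day
[morphology] best model: ~ wing_mm
[overlap] best model: ~ 1
trip-distance slope: +0.772
permutation mean_trip_distance_km: T=+0.654  p=0.0010
permutation dives_per_day: T=+24.347  p=0.0010
permutation wing_mm: T=-0.434  p=0.0020
```

Reading this: model selection picks exactly the traits that carry the
configured pairing structure — mean trip distance and dive rate with
positive slopes (real mates more different than randomized pairs), wing
length with a negative slope (real mates more similar) — while core-area
overlap adds nothing over the null.  The permutation statistics agree: real
pairs differ by +0.65 SD more in trip distance and ~24 more dives/day than
the average potential pair, and are 0.43 mm closer in wing length, each far
outside the random-matching null.  The run directory contains the CSV
artifacts (`steps.csv`, `trips.csv`, `dives.csv`, `bird_metrics.csv`,
`ba_overlap.csv`, `pair_table.csv`, `model_selection_*.csv`) and
`results.json`.

The same chain is available from a shell:

```bash
pairforage simulate --out fixtures/         # write track/depth/metadata CSVs
pairforage run --seed 1 --out murre_run     # full pipeline
pairforage report murre_run                 # summarize results.json
```

Stage subcommands (`classify`, `trips`, `spaceuse`, `pairs`) run any prefix
of the chain.

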