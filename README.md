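# episodelog

Search-log analysis of episodic interest in mood-stabilizing drugs
(MSD). People with cycling mood disorders (e.g. bipolar disorder) are
prescribed drugs such as lithium and valproate; web-search queries
naming those drugs identify a population with intensive MSD interest,
and the days on which such queries are posted behave like behavioral
event anchors. This package implements that analysis as a tested,
reproducible pipeline for researchers in infodemiology and digital
mental-health surveillance:

1. **`synthlogs`** — a seeded generator of synthetic search logs,
   demographic panels and ground truth with the episodic structure the
   analysis targets (gamma-renewal episode bursts, ~2× query-rate
   elevation on episode days, morning-pulse category elevation,
   single-drug loyalty, lithium-battery noise, gender/age marginals),
   so every stage is testable without proprietary log data.
2. **`lexicon`** — query classifiers: MSD detection with lithium
   disambiguation ("lithium dosage" counts, "lithium ion battery" does
   not), a transparent 63-category topical keyword taxonomy, and
   first-person / other-person mood-mention detection.
3. **`cohort`** — population assignment (Recurring / Occasional /
   LithiumOnly), MSD-day vs other-day query rates with a paired sign
   test, drug loyalty, MSD-term buckets, satisfied-click (first click,
   ≥30 s dwell) domain tables, and cohort-vs-panel demographics.
4. **`eventsync`** — event-synchronized likelihood curves: for category
   *c* and hourly offset *t* from MSD-query days,
   `ratio(t) = P(c | t) / P(c)`, smoothed with a centered 5-hour moving
   average, plus diurnal/weekday MSD profiles with KS tests.
5. **`features` / `predict`** — the 1,981-attribute daily
   representation (132 base attributes × [current day + 13 trailing
   windows + divergence from the user's non-MSD baseline] + day of
   week) and next-day MSD-query prediction with decision trees under
   user-level 5-fold cross-validation, reported as pooled AUC.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data (sizes scale with `--scale`):

```bash
python analysis/01_simulate.py --seed 1 --scale 0.3
python analysis/02_cohort_descriptives.py
python analysis/03_event_sync.py --seed 1
python analysis/04_predict.py --seed 1
```

Output from that run (450 users, ~800k queries):

```
queries/day on MSD days 15.7 vs other days 9.6 (ratio 1.64, sign-test p=8.4e-44)
single-drug: 99.92% of drug-name queries, 97.92% of users, 97.3% of high-interest users
female fraction cohort 59.79% vs control 49.81% (z=2.10, p=0.036)
hour-of-day KS p=1.7e-87, day-of-week KS p=0.012 (6265 MSD vs 797076 other queries)
nutrition peak ratio raw 3.68 at +58h, smoothed 3.39 at +82h
business  peak ratio raw 2.91 at +106h, smoothed 2.30 at +106h
adult     peak ratio raw 2.03 at +105h, smoothed 1.83 at +106h
null generator: 3.0% of bins deviate from 1 by more than 0.2 (mean ratio 0.984)
Recurring    pooled AUC 0.714 (per-fold mean 0.713, 150 users, 27149 user-days)
             top attributes: base_unusual_count, base_active_hours, base_n_health, ...
LithiumOnly  pooled AUC 0.468 (per-fold mean 0.470, 90 users, 16288 user-days)
recurring vs lithium-only AUC difference: bootstrap p=0.0040
adult-outcome variant: pooled AUC 0.654 (385 users with >=5 adult-query days)
```

Reading these numbers: users query roughly twice as much on the days
they post MSD queries (the 0.3-scale run attenuates the ratio; at the
full 500-user recurring population it recovers ≈ 1.93 of the configured
2.0); nutrition interest around MSD days peaks near the configured 3.3×
likelihood ratio; MSD queries skew toward weekday mornings; and a
decision tree over lagged daily-activity features predicts *tomorrow's*
MSD query well above chance for the recurring population, at chance for
the lithium-only population (whose "lithium" queries have no episode
structure), with night-hour activity and health-query counts among the
most selected attributes.

A one-command replication (simulation → classification → cohort →
curves → prediction, with a manifest of all seeds and parameters) is:

```bash
episodelog run-all --seed 1 --out results/pipeline
```

and the `episodelog simulate|classify|cohort|sync|features|predict`
subcommands expose the individual stages on TSV/YAML files.

## Layout

```
src/episodelog/     library: logio, lexicon, synthlogs, cohort,
                    eventsync, features, predict, pipeline, cli
analysis/           numbered study drivers (simulate → descriptives →
                    event sync → prediction)
scripts/            acceptance.py
tests/              pytest suite (unit, property, acceptance)
docs/methods.md     models, assumptions, parameter choices, limitations
```
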