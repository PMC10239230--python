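# birdquiz

Adaptive multiple-choice species-identification training, end to end and
without human subjects: a species catalog with expert-designated similar-song
pairs, a proficiency-driven quiz engine with a review-probability mechanism,
a forgetting-curve learner simulator, a randomized two-arm experiment
protocol, and descriptive metrics over the resulting event logs.

## What it does

- **Catalog** (`birdquiz.catalog`) — a validated 26-species roster (CSV,
  bundled) with a symmetric similar-species relation at two difficulty
  levels (E = easier, D = more difficult).
- **Engine** (`birdquiz.engine`) — five-choice quiz generation. Adaptive
  mode tracks a per-species proficiency level (+1 on correct; −1 on the
  correct species and the chosen distracter on a miss, floored at 0),
  treats level ≥ 3 as "mastered", draws the correct choice from the
  unmastered pool except for reviews with probability
  `P = p·w·Nu / (Nu + w·Nm)` (defaults p = 0.25, w = 0.5), and composes
  distracters by proficiency tier (high-proficiency foils at low levels,
  low-proficiency and similar-song foils at high levels). Baseline mode
  draws everything uniformly.
- **Learner simulator** (`birdquiz.learner`) — exponential forgetting
  `2^(−Δt/half-life)` with multiplicative, spacing-sensitive consolidation,
  similarity-driven confusion when recall fails, and a per-species
  memorability multiplier shared across a cohort.
- **Protocol** (`birdquiz.protocol`) — pretest (day 0), 50-question
  training sessions on days 1/2/4/5, midterm (day 3), posttest (day 6) and
  a delayed test (day 20); tests present all 26 species as choices and give
  no feedback. Fully reproducible from `(master_seed, participant_id)`.
- **Metrics** (`birdquiz.metrics`) — test scores, per-species training
  question counts, inverse lag times (/days), median question intervals
  (in questions), accuracy ± binomial SE, confusion matrices, and a
  permutation test for arm contrasts. CSV exports throughout.

## CLI

```sh
# simulate a 30+30 cohort; writes JSON-lines logs, metrics CSVs, summary.txt
birdquiz simulate --seed 1 --out runs/demo

# recompute every metrics CSV from the logs alone
birdquiz metrics --in runs/demo/logs --out runs/reanalysis

# play the quiz yourself at the keyboard
birdquiz quiz --mode adaptive
```

`simulate` accepts `--config cfg.json` with flat keys (e.g.
`{"questions_per_training_day": 25, "review_weight": 0.5}`); flags override
the file, the file overrides defaults. Output is a pure function of
(config, seed): rerunning with the same seed is byte-identical.

## Library sketch

```python
import birdquiz as bq

catalog = bq.builtin_catalog()
logs = bq.run_cohort(
    30, catalog, bq.LearnerConfig(), bq.EngineConfig(), bq.ProtocolConfig(),
    master_seed=1,
)
posttest = [bq.test_scores(l)["posttest"] for l in logs if l.arm == "adaptive"]
acc, se = bq.species_accuracy(logs, "Moci", "posttest", "adaptive")
```
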