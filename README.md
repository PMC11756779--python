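# syntharm

Tools for building and evaluating **synthetic external control arms** for
survival (time-to-event) trials from small tabular clinical datasets.

The package covers the full pipeline:

1. **Typed trial tables** (`syntharm.trial_data`) — CSV I/O against a
   declared schema (binary / categorical / continuous columns with
   survival-time, event-indicator and arm roles), validation, hold-out
   splitting.
2. **Reversible data generalization** (`syntharm.generalization`) —
   quantile binning of high-cardinality continuous features before
   synthesis, and reversal afterwards by sampling truncated normal
   distributions whose per-bin mean/sd are estimated under the Laplace
   mechanism (differential privacy), with explicit epsilon accounting.
3. **Generators** (`syntharm.generators`) — Dummy (replication upper
   bound), Uniform (marginal lower bound), Independent, and a native
   PrivBayes-style DP Bayesian network (exponential-mechanism structure
   search + Laplace-noised conditionals), plus an `external` plugin
   contract for attaching third-party generators behind the same
   fit/sample interface.
4. **Evaluation** — resemblance (`syntharm.resemblance`: KS statistic,
   Jensen–Shannon distance, train-on-original vs train-on-synthetic
   classifier agreement), utility (`syntharm.utility`: Cox beta distance,
   KM median distance, survival-curve area distance, predicted-survival
   distance from spline-baseline proportional-hazards models), and privacy
   (`syntharm.privacy`: categorical attribution score, boosted-tree
   detection AUROC, distance-to-closest-record and nearest-neighbor
   distance ratio with hold-out baselines).
5. **Ranking** (`syntharm.ranking`) — per-measure ranks aggregated to
   min–max-normalized rank scores per category (lower = better).
6. **Cohort fixture** (`syntharm.fixture`) — a simulated two-arm oncology
   cohort (Weibull proportional hazards, uniform accrual, administrative
   censoring, mostly balanced binary covariates) so the whole stack runs
   without any external data.
7. **Benchmark & hybrid analysis** (`syntharm.benchmark`, CLI) — the
   fit → generalize → synthesize → reverse → evaluate → rank loop, and the
   hybrid dataset (synthetic control + original active arm) with
   bootstrapped Cox hazard ratios.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (fixture cohort
shape, reference-bound rank ordering, generalization roundtrip and DP
calibration, metric oracles, utility identity, privacy flags, and the
generalization-benefit direction). The heaviest acceptance test runs a
10-repetition paired benchmark and takes a few minutes.

## CLI

```sh
syntharm simulate -o cohort.csv --schema schema.yaml --seed 1
syntharm benchmark -i cohort.csv --schema schema.yaml -c bench.yaml -o out/
syntharm hybrid --synthetic synth.csv --active active.csv --schema schema.yaml -o hy/
syntharm report -i out/
```

A benchmark config is a small YAML document:

```yaml
generators:
  - {kind: dummy}
  - {kind: uniform}
  - {kind: privbayes, hyperparameters: {epsilon: 10.0, max_parents: 2}}
n_runs: 10
holdout_fraction: 0.2
generalize: true
n_bins: 10
generalization_epsilon: 10.0
seed: 0
```

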