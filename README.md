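# viscoweber

Statistical pipeline for two-alternative forced-choice (2AFC)
viscosity-discrimination experiments: a log-domain erf psychometric model
parameterized directly by the Weber fraction, constrained maximum-likelihood
fitting, participant-resampling bootstrap inference for Weber fractions and
points of subjective equality (PSE), appearance-bias and difference testing,
rank-based per-subject robustness checks, and a synthetic 2AFC observer
generator so every stage is testable without human data.

## Model

The probability of judging a test stimulus of viscosity `η` thicker than a
reference `p` is

```
f(η) = 0.5 + 0.5 · erf( log(η/p) / (√2 · log(w + 1)) )
```

a cumulative Gaussian in log viscosity whose slope is the Weber fraction `w`:
`f(p·(1+w)) ≈ 0.8413` (the 84% discriminability threshold) and the
just-noticeable-difference bounds are `p/(1+w)` and `p·(1+w)`. Fits run in
two modes — `fixed_p` (p pinned at the true reference; `w` is the Weber
fraction) and `free_p` (`p` fitted as the PSE; its displacement from the
reference is the perceptual bias) — by maximizing an independent-binomial
likelihood over pooled per-pair counts, within box bounds
`w ∈ [0.1, 100]`, `p ∈ [10, 20500]`, initial values `(0.5, p_true)`.

Confidence intervals come from a participant-resampling bootstrap (default
5000 iterations): per stimulus pair, responses are resampled with
replacement and the model refitted; percentile intervals, mean differences
(Δ), empirical and normal-tail p-values, Bonferroni correction, and the
CI-width ≥ 2 exclusion rule for poorly constrained Weber fractions all
operate on the resulting draw arrays.

## Layout

| module                    | contents                                                        |
| ------------------------- | --------------------------------------------------------------- |
| `viscoweber.data`         | stimulus/design containers, trial CSV I/O, aggregation, screening, per-subject percentages |
| `viscoweber.presets`      | bundled 21-sample stimulus inventory, A–E groupings, task presets |
| `viscoweber.psychometric` | model, likelihood, constrained ML fitting, JND                  |
| `viscoweber.bootstrap`    | resampling, percentile CIs, difference/bias tests, exclusion    |
| `viscoweber.ranktests`    | Mann–Whitney U and Wilcoxon signed-rank (normal + exact)        |
| `viscoweber.simulate`     | synthetic observers, appearance-gain bias, lapse, heterogeneity |
| `viscoweber.cli`          | `viscoweber` command-line pipeline                              |

## CLI

```bash
viscoweber all --config config.yaml --seed 1 --out results/
```

Subcommands `simulate`, `fit`, `bootstrap`, `compare`, `report` run the
individual stages; `all` chains them. The config is YAML (all keys optional):

```yaml
task: task1a        # task1a|task1b|task1c|task2|task3a|task3b
n_subjects: 57      # override the preset cohort size
iterations: 5000    # bootstrap iterations
alpha: 0.01
n_comparisons_bias: 5
```

Artifacts are plain CSV/JSON: `trials.csv`, `response_tables.csv`,
`fits.json`, `bootstrap_<group>.csv/.json`, `comparisons.csv`,
`weber_table.csv` (excluded fits rendered `N/A`), `jnd_table.csv`,
`bias_table.csv` (free-p tasks), `subject_check_table.csv`, `screening.csv`,
plus a `resolved_config.json` snapshot with input hashes. Runs are
byte-for-byte reproducible given the same inputs, config and seed.

## Python API sketch

```python
import viscoweber as vw

config = vw.scenario("task1a", seed=1)          # preset design + observer
trials = vw.simulate_experiment(config)
groups = vw.build_group_designs(vw.builtin_stimuli("transparent"))
table = vw.aggregate(trials, groups[2])          # group C
fit = vw.fit(table, "fixed_p", true_reference=1560.0)
sample = vw.bootstrap_fit(table, iterations=5000, seed=1)
ci = vw.percentile_interval(sample.w_draws, 95)
```

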