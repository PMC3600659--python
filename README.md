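# revlearn

Simulation and analysis pipeline for feedback-driven decision making:
a probabilistic reversal learning task (PRLT) engine, synthetic
reinforcement-learning cohorts, behavioral dependent measures,
feedback-locked ERP synthesis and scoring (FRN / P3), correlation-based
cortical source mapping, and repeated-measures statistics — chained by a
reproducible end-to-end study runner.

## What it does

* **`revlearn.task`** — PRLT schedules: 4 phases x 40 trials, the
  correct option flips at every phase boundary, reward contingencies
  (75% / 87.5%) are realized by exact-count false-feedback scheduling,
  every feedback is worth +/-5 points.
* **`revlearn.cohort`** — synthetic participants in three groups
  (HC 23 / PG 21 / CDI 20): interview-style exposure composites
  (intensity = amount x frequency, severity = amount x frequency x
  duration), a softmax delta-rule agent with valence-specific learning
  rates, lapse, stickiness, and a log-normal latency model.  Exposure
  acts through within-group rank scores: severity raises lapse
  (suppressing the asymptote); intensity slows feedback learning
  (raising reversal cost) and slows decisions.
* **`revlearn.behavior`** — correct choices per 10-trial block,
  first-block reversal-cost scores, collapsed last-two-block asymptote
  scores, rank transforms and residual-based partial correlations.
* **`revlearn.eegsim`** — synthetic feedback-locked epochs (-200..+350
  ms at 250 Hz) built from compact-support Gaussian components whose
  differential FRN at FCz is calibrated exactly on the sampling grid;
  voxel current-density maps whose per-area density-FRN correlations
  match configurable targets.
* **`revlearn.erp`** — +/-100 uV artifact rejection (strict bound),
  baseline-corrected condition averaging, FRN (220-350 ms mean minus
  the 150-220 ms positive peak) and P3 (last 50 ms vs preceding 100 ms)
  component scores and their differentials.
* **`revlearn.sources`** — window-averaged voxel densities (220-330
  ms), voxelwise density-FRN Pearson correlations (parametric or
  bootstrap p), the >= 10-significant-voxel area rule, and Fisher-z
  cross-group correlation contrasts with Bonferroni adjustment.
* **`revlearn.stats`** — mixed repeated-measures ANOVA (orthonormal
  contrast decomposition, Greenhouse-Geisser epsilon applied on a
  Mauchly pretest), repeated-measures ANCOVA with continuous
  covariates, Bonferroni / LSD pairwise post hocs.
* **`revlearn.study`** — master-seeded orchestration of all stages with
  labelled per-stage substreams; re-running a configuration reproduces
  byte-identical outputs.

## CLI

```bash
revlearn run-study --seed 7 --out out/study7        # full pipeline
revlearn simulate-cohort --seed 1 --out out/manifest.csv
revlearn simulate-behavior --seed 1 --out out/trials.csv
revlearn score-behavior --trials out/trials.csv --out out/metrics.csv
revlearn synth-eeg --seed 1 --frn-differential 3.0 --out out/ep
revlearn score-erp --epochs out/ep --out out/scores   # also: score-erp
revlearn synth-sources --frn out/scores/frn_scores.csv --out out/density.csv
revlearn map-sources --density out/density.csv --frn out/scores/frn_scores.csv \
    --alpha 0.05 --min-voxels 10                      # also: map-sources
revlearn stats --metrics out/metrics.csv --out out/anova.csv
revlearn report --study-dir out/study7
```

`run-study` accepts a YAML configuration mirroring the dataclass fields
(`revlearn.study.load_study_config`), e.g.

```yaml
master_seed: 7
task:
  contingencies: easy-early
cohort:
  group_sizes: {HC: 23, PG: 21, CDI: 20}
scoring:
  rejection_threshold: 100.0
```

## Notes

* Epoch containers are a raw `.npy` array plus a JSON sidecar
  (channels, sampling rate, times, condition labels); all other
  artifacts are CSV/JSON.
* The synthetic agent is a stand-in for unavailable participant data:
  effect maps are calibrated so the qualitative effect structure
  (severity -> lower asymptote, intensity -> higher reversal cost and
  slower decisions, reduced FRN in gamblers) is recoverable at
  realistic sample sizes, not to reproduce any real-data statistics.
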