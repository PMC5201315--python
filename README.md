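# fatiguelab

Driving-fatigue analysis pipeline built around reaction-time probes and
physiological signals:

* **`fatiguelab.synthdata`** — synthetic driving sessions (EEG as band-limited
  noise whose alpha/beta power ratio rises with fatigue level, RR-interval
  series with level-dependent dispersion, choice reaction times sampled every
  3 min, 3-level self-assessment labels over a three-period session
  structure), plus cohort generation with an exact gender mix.
* **`fatiguelab.features`** — 60-s epoching, Welch-PSD band energies
  (delta/theta/alpha/beta/broadband), spectral ratio indices, heart rate,
  RR-interval standard deviation (population SD), Haar-wavelet denoising, and
  assembly of the nine-factor feature table aligned to each reaction-time
  sample.
* **`fatiguelab.grey`** — grey relational analysis: preprocessing (min–max or
  initial-value transform), correlation coefficients with resolution ratio
  phi, correlation degrees and factor ranking.
* **`fatiguelab.gasvm`** — hierarchical two-stage binary RBF-SVM classifier
  (level 3 vs levels 1–2, then level 1 vs 2) with penalty C and kernel width
  g found by a real-coded genetic algorithm maximizing stratified K-fold CV
  accuracy (roulette selection, arithmetic crossover, boundary-decaying
  mutation, elitism of one).
* **`fatiguelab.evaluate`** — 3×3 confusion matrices, both stages' six derived
  rates, between-level reaction-time growth rates, and rolling reaction-time
  volatility.
* **`fatiguelab.pipeline`** — one seeded, reproducible run of
  simulate → features → grey ranking → GA-SVM training → evaluation.

## CLI

```bash
fatigue-simulate --n-subjects 2 --seed 1 --out cohort/           # session dirs
fatigue-features --session cohort/S000 --out table.csv           # feature table
grey-rank --features table.csv --phi 0.5 --preprocess normalize --out rank.csv
fatigue-train --features table.csv --pop 20 --gens 200 --cv 10 --seed 1 --out model.json
fatigue-eval --pred pred.csv --truth truth.csv --report report.json
fatigue-pipeline run --config run.yaml --out run_out/            # end to end
fatigue-pipeline run --quick --out run_out/                      # CI-scale
```

A pipeline config is a YAML mapping with optional `sim`, `grey`, `ga`
sections mirroring `SimConfig`, `GreyConfig` and `GAConfig` fields, plus
`seed`, `n_subjects`, `train_n`, `test_n`.

## Notes

* RT noise and RR dynamics use Gaussian stand-ins: only per-level
  means/dispersions are constrained by the source data, not distributional
  forms.
* The `alpha_over_beta` and `alpha_over_beta_psd` table columns are computed
  by the same band-power ratio (a single signal path exists here); both are
  kept to preserve the nine-factor layout, and exact grey-degree ties between
  them resolve in favor of `alpha_over_beta`.
* The grey degree divides by n by default (bounded by 1); the literal
  divide-by-(n−1) variant is selectable via `degree_denominator="n_minus_1"`.
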