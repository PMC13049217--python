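# opiscore

Objective performance indicators (OPIs), gated rubric scoring against
expert norms, and full psychometric calibration for robotic-surgery skill
assessment — with a synthetic-data module standing in for recorder data.

The pipeline:

1. **`opiscore.synth`** — simulate instrument kinematics (50 Hz pose
   streams built from minimum-jerk submovements, tremor, pauses), console
   events (energy bursts, clutch presses), Rasch-model response matrices,
   and a reference cohort of 65 scored trainees + 7 experts whose video
   outcomes carry fixed failure counts (15 bleeding, 7 tissue/tension,
   43 clean; 13 female / 17 male subgroup labels in the 2023 half).
2. **`opiscore.opi`** — the six OPI metrics per performance: speed peaks,
   angular path length, linear path length, idle time, energy proportion,
   clutch count (mm / rad / s).
3. **`opiscore.scoring`** — expert norms (mean ± 2 SD credit interval),
   the gated 12-item rubric (a failed video item 1–6 zeroes everything
   after it), and four-level competency assignment
   (completion / safety / economy / optimized).
4. **`opiscore.rasch`** — dichotomous Rasch model via MML-EM with
   Gauss–Hermite quadrature; EAP and WLE (Warm) person estimates;
   EAP/WLE reliability; infit/outfit item fit with flagging
   (default band 0.7–1.3).
5. **`opiscore.validity`** — percent agreement and Cohen's kappa,
   item–ability (point-)biserial correlations, construct-alignment
   Spearman rho, Wright map with level banding checks, and subgroup
   fairness via per-group difficulty refits with CI-overlap DIF flags.
6. **`opiscore.io` / `opiscore.pipeline` / `opiscore.cli`** — CSV schemas,
   YAML configuration, logging, and the end-to-end command line.

## CLI

```sh
opiscore run out/ --seed 1              # full pipeline on the reference cohort
opiscore simulate streams/ --seed 1     # write per-subject kinematics/events CSVs
opiscore extract streams/ opis.csv      # six OPI metrics per subject
opiscore score opis.csv outcomes.csv expert_opis.csv scores.csv
opiscore calibrate scores.csv cal/      # Rasch item/person estimates
opiscore validate scores.csv report.json
```

Every command accepts `--config config.yaml` (see `opiscore.pipeline.
PipelineConfig` for the schema; all defaults are overridable: OPI signal
thresholds, rubric level rule, quadrature, fit bounds, fairness groups).
`opiscore run` writes OPI tables, the score matrix, calibration item/person
CSVs, Wright-map coordinate tables, `summary.json`, and a stage log.

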