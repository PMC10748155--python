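# cardiostack

Multimodal cardiac-screening pipeline: heart-sound (phonocardiogram, three
auscultation sites) and scanned 12-lead ECG image classifiers whose anomaly
probabilities are fused by stacked tree-ensemble meta-learners, with
bootstrap model comparison and modality-contribution analysis. Because the
clinical recordings cannot be shared, the package ships a disease-conditioned
synthetic cohort generator that emulates the acquisition shapes exactly
(15-s / 4000-Hz WAVs, 3187 x 1840-px scan pages) so every stage is testable
end to end.

## Components

| module | role |
| --- | --- |
| `cardiostack.synthetic` | synthetic patients: three-site PCG WAVs, rendered ECG pages, ordinal AS/MR/LVD grades |
| `cardiostack.pcg` | severity-dependent segmentation, 243 x 128 log-Mel spectrograms, SpecAugment, mixup |
| `cardiostack.ecg` | 12-lead / limb / precordial crops (1840² → 512², 960² → 256²), horizontal shift augmentation |
| `cardiostack.cnn` | pure-NumPy 10-block CNN (batchnorm in blocks 1 and 10, max-pool after 4/6/9/10, global average pool, 2-way softmax), training loop, record-level inference |
| `cardiostack.stacking` | the four stacking patterns, random-forest and gradient-boosted meta-learners, F1 grid search |
| `cardiostack.stats` | rank-based AUC, bootstrap metric resampling (B = 2000), ANOVA + Tukey-Kramer comparison, top-3 selection |
| `cardiostack.contribution` | repeated-seed (R = 50) importance aggregation per modality |
| `cardiostack.folds` | modified stratified 4-fold structure: shared test set + four disjoint dev blocks |
| `cardiostack.pipeline` / `cardiostack.cli` | experiment orchestration and command-line surface |

Per disease the experiment graph trains 6 sources x 4 folds = 24 single-modal
CNNs and evaluates 14 variants per fold (6 single-modal + 4 stacking patterns
x 2 meta-learners).

## CLI

```sh
# synthesize a cohort
cardiostack simulate --profile tiny --seed 3 --n 60 --out cohort/

# full pipeline: folds -> 24 CNNs -> stacking -> evaluation -> contribution
cardiostack run-all --profile tiny --seed 3 --disease AS --out results/

# individual stages (reuse cached prediction tables)
cardiostack preprocess --cohort cohort/ --disease AS --out prep/
cardiostack train    --cohort cohort/ --disease AS --out results/ [--dry-run]
cardiostack evaluate --cohort cohort/ --disease AS --out results/
cardiostack contribute --cohort cohort/ --disease AS --out results/
cardiostack report --out results/ --disease AS
```

Configuration can also be given as a JSON/YAML document via `--config`;
invalid documents exit with status 2 before anything is written.

## Output formats

WAV: 16-bit PCM mono, 4000 Hz. Scans: single-channel PNG. Cohort manifest:
`manifest.csv` (patient_id, three PCG paths, scan path, three grades, split,
fold) plus `manifest_meta.json` with generator ground truth (systolic
windows, QRS widths, per-patient seeds). Evaluation artifacts: `folds.csv`,
`test_eval_<disease>.csv`, `bootstrap_<disease>.csv` (model, AUC/F1/
sensitivity/specificity mean and SD), `comparison_<disease>.json`,
`top3_<disease>.json`, `contribution_<disease>.csv` (model, fold, source,
mean, sd, R).
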