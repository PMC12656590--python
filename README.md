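# bcgaf

Atrial-fibrillation (AF) screening from multi-site **ballistocardiograms**
(BCG): the micro-vibrations a sleeping person's heartbeat induces in a bed,
recorded by piezoelectric sheet sensors placed under the mattress at 0, 25,
45 and 65 cm from the head (BCG1–BCG4; BCG2 sits at chest level).

## The problem and the method

In sinus rhythm the heart beats nearly periodically, so the power spectrum
of a BCG window shows a *harmonic comb*: peaks at the heart-rate frequency
(~1 Hz) and its integer multiples, prominent below ~10 Hz. Atrial
fibrillation makes the RR intervals irregularly irregular, which destroys
the comb. `bcgaf` turns this contrast into a block-level classifier:

1. **Segment** each channel into 32.768 s blocks sliding every 4.096 s
   (16,384 / 2,048 samples at 500 Hz; a 5 min recording yields 66 blocks).
2. **Reject motion artifacts**: drop blocks whose raw amplitude exceeds
   34,000 ADC counts (or, alternatively, a threshold on the standardized
   amplitude calibrated to exclude the same fraction of blocks).
3. **Standardize** each block to zero mean and unit variance, apply a
   **Hanning-windowed FFT** (8,193 one-sided power points on 0–250 Hz),
   crop to a `[lowcut, highcut]` band and sum power into `nbins`
   equal-width bins.
4. **Tune** decision-tree, random-forest, logistic-regression and AdaBoost
   classifiers jointly over featurization settings and hyperparameters with
   **stratified group 5-fold CV** — participants, never blocks, are split,
   so no subject leaks across folds — and probe generalization with
   leave-one-participant-out CV.
5. **Evaluate** block-level accuracy, recall, specificity, precision,
   F1 = 2·r·p/(r+p) and ROC-AUC, including applying a model trained on one
   sensor to blocks recorded by another (robustness to sensor placement).
6. **Fuse** sensors at decision level with the **OR rule**: a time-aligned
   block is AF if any available sensor says AF, and is excluded only when
   every chosen sensor failed noise rejection.

No public BCG recordings exist for this setting, so the package ships a
first-class synthetic generator (`bcgaf.synth`): beat times from a
truncated-normal (sinus, RR CV 0.03) or log-normal (AF, RR CV 0.24) renewal
process, rendered through a damped-oscillation kernel with
placement-dependent cardiac/respiratory gains, a ~32,800-count DC offset,
white noise, and Poisson motion bursts exceeding the 34,000-count
threshold. Everything downstream is exercised end-to-end on this cohort.

## Worked example

```python
from bcgaf import Family, SensorPlacement, SynthParams
from bcgaf.classify import ClassifierConfig, cross_location_apply, fit_model, grid_search
from bcgaf.preprocess import featurize_recordings
from bcgaf.synth import generate_cohort
from bcgaf.types import SpectrumSetting

params = SynthParams()                      # 300 s, 500 Hz, 4 sensors
train = generate_cohort(6, 11, params, seed=11, placements=[SensorPlacement.BCG2])
test = generate_cohort(2, 4, params, seed=12, placements=[SensorPlacement.BCG2])
for rec in test:
    rec.participant_id = "T" + rec.participant_id

settings = [SpectrumSetting(0.0, 10.0, 30), SpectrumSetting(1.0, 10.0, 30)]
train_ds = featurize_recordings(train, None, settings)
test_ds = featurize_recordings(test, None, settings)
print(train_ds.n_included, "of", train_ds.n_total_blocks, "blocks pass the noise screen")

grid = [ClassifierConfig.make(Family.ADA, s, learning_rate=lr, max_depth=md)
        for lr in (1.0, 0.9) for md in (1, 7) for s in settings]
best = grid_search(train_ds, grid, k=5, seed=0)
print("best CV accuracy:", round(best.mean_accuracy, 3), "at", best.config.setting)

model = fit_model(train_ds.features[best.config.setting],
                  train_ds.meta["label"].to_numpy(), best.config, seed=0)
report, _ = cross_location_apply(model, test_ds)
print(report.rounded())
```

Output:

```
913 of 1122 blocks pass the noise screen
best CV accuracy: 0.996 at 0-10Hz_30bins
{'tp': 104, 'fp': 0, 'tn': 210, 'fn': 0, 'accuracy': 1.0, 'recall': 1.0,
 'specificity': 1.0, 'precision': 1.0, 'f1': 1.0, 'auc': 1.0}
```

913/1122 ≈ 81 % of blocks survive the 34,000-count screen (the rest overlap
injected motion bursts); the 0–10 Hz / 30-bin featurization wins the grid,
and the chest-sensor AdaBoost model separates the synthetic test cohort
perfectly — the generator's two rhythm classes are spectrally well
separated by design.

The same flow is available from the shell:

```bash
bcgaf run --out demo_run          # full pipeline on the built-in demo config
bcgaf simulate --n-af 2 --n-non-af 3 --seed 7 --out cohort/
bcgaf featurize --in cohort/ --placement BCG2 --out features.csv
```

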