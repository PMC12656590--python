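# Methods

## Signal model of the synthetic cohort

A bed-mounted piezoelectric sheet records a superposition of cardiac
vibration, respiration-driven deformation, electronic noise and body
motion, digitized by a 16-bit unsigned ADC (counts 0–65,535) at 500 Hz
with a DC operating point near 32,800 counts. The generator in
`bcgaf.synth` models one channel as

```
x(t) = dc_offset
     + g_card(placement) · (Σ_i δ(t − t_i)) * k(t)
     + g_resp(placement) · sin(2π f_resp t + φ)
     + ε(t),            ε ~ N(0, noise_sd²)
k(t) = exp(−t/τ) · sin(2π f_k t)
```

rounded and clipped to the ADC range. The damped-oscillation kernel
`k` (carrier `f_k` = 5 Hz, decay τ = 0.15 s) is a minimal stand-in for
the mechanical impulse response of a body–mattress system to one
ventricular ejection: it is not a morphological model of any particular
device, but it reproduces the property the classifier exploits — a
near-periodic impulse train convolved with any fixed kernel yields a
spectral comb at multiples of the beat rate, with energy concentrated
below ~10 Hz.

Beat times `t_i` form a renewal process. Sinus rhythm draws RR
intervals from a normal distribution with mean `60/HR` and coefficient
of variation 0.03, truncated below at 0.2 s (a physiological floor that
in practice never binds at CV 0.03). AF draws i.i.d. log-normal
intervals with the same mean and CV 0.24. High-CV i.i.d. intervals are
sufficient to destroy the comb; no attempt is made to model the
autocorrelation structure of real AF ventricular response.

Parameters, units and defaults:

| parameter | default | meaning |
|---|---|---|
| `duration_s` | 300 s | recording length (66 analysis blocks) |
| `fs` | 500 Hz | sampling rate |
| `mean_hr_bpm` | 66 | cohort mean heart rate; per-participant jitter SD `hr_jitter_bpm` = 8, clipped to 40–140 |
| `rr_cv_sinus` / `rr_cv_af` | 0.03 / 0.24 | RR-interval coefficient of variation per rhythm |
| `kernel_freq_hz`, `kernel_decay_s` | 5 Hz, 0.15 s | beat kernel carrier and decay |
| `resp_freq_hz` | 0.25 Hz | respiration rate (~15 breaths/min) |
| `dc_offset` | 32,800 counts | ADC operating point |
| `cardiac_gain_by_placement` | 700 / 900 / 400 / 200 | BCG1–4 beat-response amplitude, counts |
| `resp_gain_by_placement` | 100 / 80 / 300 / 350 | BCG1–4 respiratory amplitude, counts |
| `noise_sd` | 25 counts | white sensor noise |
| `artifact_rate_per_min` | 0.4 | Poisson motion-burst rate |
| `artifact_amplitude` | 2,000 counts | burst peak above `dc_offset` |

The gain profiles encode the qualitative anatomy: the chest-level
sensor (BCG2, 25 cm from the head) carries the strongest cardiac
signal; the lumbar/sacral sensors (BCG3/4) sit near organs that move
with respiration and carry relatively more respiratory power. The head
sensor (BCG1) is cardiac-dominant like BCG2 but weaker. Absolute
values were chosen once so that per-block maxima/minima of clean
signal sit several hundred counts either side of the DC offset — the
amplitude scale reported for real recordings of this kind — while
clean blocks stay safely below the 34,000-count artifact threshold
(clean BCG2 peaks near 33,600 counts, leaving a ~400-count noise
margin).

Motion bursts are Poisson events of 0.5–2 s that *replace* the affected
samples with `dc_offset + artifact_amplitude · hann(t) · cos(2π·8·t)`,
with the envelope peak normalized so the burst attains exactly
`dc_offset + artifact_amplitude` (34,800 by default). This guarantees
every burst exceeds the 34,000-count screen whenever
`dc_offset + artifact_amplitude > 34,000`, which the generator
enforces. A rate of 0.4/min makes ~20 % of sliding blocks overlap a
burst (one burst contaminates ≈8 consecutive 32.768 s windows at the
4.096 s stride), matching the order of block exclusion reported for
real supine recordings at this threshold.

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawning: one child per participant, and
fixed sub-streams per participant for heart-rate jitter, beat times,
each channel's noise/phase and each channel's artifacts. Identical
seeds therefore give bit-identical cohorts.

### What the generator does *not* emulate

Real BCG morphology (device-specific multi-component waveforms),
posture changes, non-supine positions, amplitude drift, respiratory
sinus arrhythmia, AF RR autocorrelation, ectopy, and inter-participant
anatomy beyond a scalar gain profile. Consequently the synthetic
classes are far more separable than human cohorts: pipeline tests
passing here demonstrate the *machinery* (segmentation, screening,
featurization, grouped CV, fusion algebra) is correct, not that the
published human-cohort performance is reproduced.

## Preprocessing conventions

- Block length is fixed at 16,384 samples (= 32.768 s × 500 Hz, a power
  of two) with a 2,048-sample stride; the trailing partial window is
  dropped. Block count obeys `floor((N − L)/S) + 1`.
- Standardization uses the population SD (divisor N). At N = 16,384 the
  difference from the sample SD is negligible, but a fixed convention is
  required for bit-reproducibility. Zero-variance blocks raise
  `DegenerateBlockError` and are excluded by callers.
- The raw noise statistic is the per-block maximum amplitude, compared
  against 34,000 counts; only the upper tail is screened. The
  standardized-rule statistic mirrors it (max of the standardized
  block). `calibrate_standardized_threshold` returns the largest kept
  order statistic such that `floor(fraction·n)` blocks exceed it; ties
  break toward excluding fewer.
- The spectrum is `|FFT(hann·x)|²/N`, one-sided, no window-gain
  compensation (classifiers only need consistent scaling): 8,193 points
  at `k·fs/N`, spanning 0–250 Hz.
- Cropping keeps `lowcut ≤ f ≤ highcut` (both ends closed, so the DC
  point belongs to a 0-Hz lowcut). Binning partitions the cropped range
  into `nbins` equal-width intervals, the last closed, and **sums**
  power per interval; summation makes total power conserved across
  binnings and the `nbins = 1` case interpretable as band power.

## Classifier tuning

The four families (DT, RF, LR, AdaBoost-over-trees) are instantiated in
scikit-learn; tuned hyperparameters are `max_depth` (DT/RF), `C` (LR),
and `learning_rate` + base-tree `max_depth` (ADA). Untouched
hyperparameters stay at library defaults, pinned by the scikit-learn
version recorded in the run manifest. The grid search jointly optimizes
featurization setting and hyperparameters (the superset of staged
readings), evaluating each config by stratified group 5-fold CV and
maximizing mean fold accuracy; ties break toward the earliest config in
the deterministic grid order (family, then hyperparameters in table
order, then settings).

Fold construction is greedy round-robin: AF participants are shuffled
and dealt across the k folds, then non-AF participants continue the
deal from where the AF deal stopped, so per-fold AF counts and fold
sizes each differ by at most one. Every fold evaluation asserts the
train/validation participant sets are disjoint.

A single-class training partition yields a constant predictor (score 0
or 1) rather than an error, so degenerate folds and
leave-one-participant-out fits remain well-defined. AUC is the
trapezoidal ROC area over the AF-class scores (equivalently the
normalized Mann–Whitney U, cross-checked in the tests); it is reported
as missing when only one class is present. Printed metrics round to two
decimals half-away-from-zero.

## Fusion semantics

Blocks align across sensors by `(participant_id, start_sample)` since
channels are recorded simultaneously. For a chosen sensor subset, the
OR rule labels a block AF if any *available* (noise-passing) sensor
predicted AF; the block is excluded only when no subset sensor has a
prediction. This "OR over available" reading is forced by the
observation that fusing sensors must *increase* the number of included
blocks — which only holds if a single surviving channel rescues a
block. Immediate algebraic consequences, verified exhaustively over all
2⁴ per-block patterns: fused recall ≥ every component recall, fused
specificity ≤ every component specificity (on blocks all components
saw), and included-block counts are monotone over the subset lattice.

## Problem sizes and numerical choices

The acceptance script and the learning tests use the study composition
— 23 AF / 44 non-AF training and 6 AF / 11 non-AF test participants,
300 s each — on the chest channel with a reduced AdaBoost grid
(learning_rate ∈ {1.0, 0.9} × max_depth ∈ {1, 7} × two settings around
the 0–10 Hz / 30-bin winner). The package's choice of a reduced grid
reflects that the synthetic classes are separable enough that the full
7,840-point table grid adds nothing but compute; `full_grid()` remains
available for exhaustive runs. Statistical property checks (harmonic
band power of sinus vs AF blocks) use a one-sided Mann–Whitney test at
α = 0.01 with ≥ 20 blocks per class.

## Known limitations

- Generator realism as listed above; in particular transfer accuracies
  across placements depend directly on the invented gain profiles.
- Only the upper amplitude tail is screened for artifacts; real
  artifacts with negative excursions below the threshold would pass.
- The fused predictions carry no scores, so fusion reports have no AUC.
- LR at extreme `C` values may not fully converge within the iteration
  cap; such grid points simply compete at whatever accuracy they reach.
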