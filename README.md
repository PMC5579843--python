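# arthroskill

Objective assessment of arthroscopic surgical skill from tool motion and
force, using normalized energy-expenditure metrics and leave-one-subject-out
(LOSO) validated expertise classification.

Surgical training programs need objective, repeatable alternatives to
expert-panel rating scales. This package implements an energy-based
approach for simulator-trained shoulder arthroscopy: each trainee trial is
summarized by how much mechanical energy the trainee expends moving the
tracked instrument and arthroscope, normalized against a single
ideal-performance reference trial, and those scores feed binary
novice-vs-expert classifiers. A synthetic trial generator reproduces the
statistical structure of such recordings (smooth goal-directed motion,
band-limited physiological tremor, switch-press forces), so the full
pipeline is exercisable and testable without human-subject data.

## The metrics

From a trial sampled uniformly at 20 Hz — tip position **p**(t) (m), unit
quaternion orientation q(t), and, for the sensorized instrument, bending
force magnitude F(t) (N) — the pipeline low-pass filters the signals
(4th-order zero-phase Butterworth, 12 Hz nominal cutoff, clamped below
Nyquist), differentiates them, and computes four per-trial scalars:

- **EP** (potential): `Σ_k |h_{k+1} − h_k|` — total variation of the height
  coordinate h along the gravity axis (units m; mass and g are common
  factors across subjects and are dropped),
- **ETK** (translational kinetic): `Σ_k |v²_{k+1} − v²_k|` for tip speed v
  (units (m/s)²; factor m/2 dropped),
- **ERK** (rotational kinetic): `Σ_k |s_{k+1} − s_k|` with
  s = ω_x² + ω_y² + ω_z² from the body-frame angular velocity (units
  (rad/s)²; factor I/2 dropped) — the discrete change integral
  `∫₀ᵀ |d(ω_x²+ω_y²+ω_z²)/dt| dt`,
- **W** (work): `Σ_k F̄_k Δs_k` — midpoint force times unsigned tip path
  increment (units N·m; absent for the arthroscope, which carries no force
  sensor).

Each metric is divided by the value from one ideal-performance reference
trial, giving dimensionless ratios (WN, EP-N, ETK-N, ERK-N) where 1 means
ideal-equivalent expenditure. Per-subject feature vectors (4 instrument
metrics, 3 arthroscope metrics, or all 7) feed four classifiers — linear
SVM, KNN (K = 3, posterior Ki/K), a d→3→1 neural network trained by
Levenberg–Marquardt with targets {1, 2} and rounded output, and Fisher LDA —
validated by LOSO cross-validation and scored by accuracy, precision,
recall and F1 (experts as the positive class). Group differences are
tested with Shapiro–Wilk-routed statistics (Welch's t when both groups
look normal, Mann–Whitney U otherwise).

## Worked example

Generate a synthetic cohort shaped like a typical study task (14 novices,
4 experts, both tools, novice-to-expert tremor ratio 4), compute metrics
and run a LOSO-validated SVM:

```bash
arthroskill simulate --novices 14 --experts 4 --task 1 --effect-size 4 \
    --seed 0 --out cohort/
arthroskill metrics  --manifest cohort/manifest.yaml --out metrics.csv
arthroskill classify --manifest cohort/manifest.yaml \
    --classifier svm_linear --out report.csv
arthroskill stats    --manifest cohort/manifest.yaml --out stats.csv
```

which prints

```
wrote 38 trials to cohort/
wrote 38 rows to metrics.csv
svm_linear on both: accuracy 100.0 precision 100.0 recall 100.0 f1 100.0
wrote 7 comparisons to stats.csv
```

The 38 trials are 18 subjects × 2 tools plus one ideal reference per tool.
In `metrics.csv`, each expert's normalized metrics sit several-fold below
the novices' (e.g. instrument EP-N ≈ 1.25 ± 0.04 for experts vs
3.14 ± 0.64 for novices in this run); at this effect size the groups are
linearly separable,
so every held-out subject is classified correctly (accuracy, precision,
recall and F1 all 100%). `stats.csv` reports, per tool and normalized
metric, group means ± SD, the routed test and its p value — at effect
size 4 all seven comparisons are significant, while with `--effect-size 1`
the groups are statistically identical and significance drops to the
nominal false-positive rate.

The same pipeline runs on real recordings by pointing the manifest at
trial CSVs (columns `t,x,y,z,qw,qx,qy,qz[,f]`; manifest declares units,
gravity axis, subject/level/task/tool per file).

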