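# Methods

This note documents the models, numerical choices and limitations behind
`arthroskill`: what the energy metrics compute, how the synthetic cohort
generator emulates simulator recordings, how the classifiers and the
validation pipeline are configured, and what the test suite does and does
not establish about real data.

## Signal model and preprocessing

A trial is a uniformly sampled (default 20 Hz) trace of tool-tip position
(metres, lab frame, +z opposing gravity unless the manifest says
otherwise), orientation (unit quaternions, scalar-first), and — for
sensorized instruments — the scalar bending-force magnitude (N). Validity
is structural: strictly increasing time with relative step deviation
≤ 1e-6, quaternion norms within 1e-3 of unity (renormalized on read),
non-negative force. Screening for tracker dropouts or interruptions is
*manual*: a `valid` flag in the manifest, not automated artifact
detection.

Position (and force, where used) channels are low-pass filtered with a
4th-order Butterworth applied forward–backward (`filtfilt`), giving zero
phase so that the difference-based metrics are not biased by group delay.
The nominal cutoff is 12 Hz. At 20-Hz sampling this exceeds the 10-Hz
Nyquist limit, so the effective cutoff is clamped to 0.99·(fs/2) = 9.9 Hz
and a warning is logged; the clamp preserves the configured intent while
remaining well-defined at any sampling rate. Orientation channels are
differentiated unfiltered by default (configurable), since quaternion
component-wise filtering does not commute with renormalization and the
angular-velocity estimator is already a per-step average.

Velocities come from central differences (one-sided at the endpoints,
exact for affine trajectories). Angular velocity uses the quaternion
logarithm: ω_k = rotvec(q_k⁻¹ q_{k+1}) / Δt, a body-frame per-step rate
that is immune to gimbal artifacts and to the q ↔ −q double cover; a
single step subtending ≥ π rad is rejected as aliased.

## The energy metrics

All four metrics are discrete total variations or path sums, with the
instrument-constant prefactors (mass, moment of inertia, g) dropped:
they are common scale factors across subjects and cancel exactly under
ideal-trial normalization. Reduced units are therefore m, (m/s)²,
(rad/s)² and N·m.

The rotational metric deserves its own paragraph because it is the one
place where a formula had to be interpreted. The change integral of
squared angular speed, taken literally as `∫ d(ω²)/dt dt`, telescopes to
ω²(T) − ω²(0), which is ≈ 0 for any trial that starts and ends at rest —
a vacuous quantity. The implementation integrates the *absolute* rate of
change, `∫ |d(ω_x²+ω_y²+ω_z²)/dt| dt`, consistent with the companion
metrics being "sums of changes" of potential and kinetic energy. The same
absolute-value convention is used for EP and ETK. This is the central
interpretive decision in the package.

Work uses the scalar bending-force magnitude times the unsigned tip path
increment (midpoint rule). The sensor measures a bending magnitude with
no direction aligned to the motion, so a signed line integral is not
available; the metric is an upper-bound-style effort proxy, which is what
skill discrimination needs. Low-pass filtering can undershoot below zero
near sharp force onsets; the filtered force is clipped at 0 before the
work sum (the raw channel is a magnitude, so negative values are filter
artifacts).

Normalization divides each metric by the corresponding value of the one
ideal reference trial per (task, tool); a zero ideal component is an
error (an ideal trial with no expenditure cannot serve as a reference),
not a silent NaN. Normalized metrics are invariant to any consistent
unit rescaling (mm vs m) of trial and reference together; raw metrics
scale as c (EP), c² (ETK) under position scaling — properties the test
suite asserts.

Key discretization property: total variation on a decimated grid never
exceeds the full-grid value (triangle inequality), so the 20-Hz metrics
are slight underestimates of the continuous-time quantities. For motion
content below ~0.5 Hz the underestimate is below 1% (the sampled-sine TV
deficit is ≈ 1 − cos(πf/fs)); tremor-band content is attenuated more,
which is acceptable because all trials pass through the same pipeline and
only ratios are interpreted.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the conditions
under which the pipeline's statistical claims are demonstrated.

One trial = minimum-jerk, rest-to-rest straight segments through a small
set of task waypoints (three tasks: two probing patterns and a
grasp-and-remove pattern, ~5 cm workspace; the arthroscope uses the same
geometry at 0.4× amplitude, reflecting its secondary role), plus
band-limited tremor (white noise band-passed to 1–8 Hz — the
physiological tremor band, chosen to survive the 9.9-Hz effective
cutoff), on position and, as a rotation-vector perturbation, on
orientation. Orientation follows the smoothed path tangent (yaw/pitch
low-passed at 2 Hz so segment changeovers stay well below the π-per-step
aliasing limit). Instrument force is a ~1-N Gaussian bump (σ = 0.4 s) at
each switch-press waypoint arrival plus non-negative sensor noise.

Expertise presets (defaults, chosen once from task scale and
physiological-tremor magnitudes):

| parameter | ideal | expert | novice(effect_size) |
|---|---|---|---|
| positional tremor RMS (m) | 0 | 2·10⁻⁴ | 2·10⁻⁴ · es |
| angular tremor RMS (rad) | 0 | 5·10⁻³ | 5·10⁻³ · es |
| duration factor | 1.0 | 1.2 | 1.2·(1 + 0.15(es−1)) |
| force peak (N) | 1.0 | 1.1 | 1.1·(1 + 0.1(es−1)) |
| force noise RMS (N) | 0 | 0.02 | 0.02 · es |

`effect_size` (es) is the novice-to-expert tremor ratio; the novice
preset is defined as the expert preset with the *excess* scaled by es, so
es = 1 collapses the two groups into one distribution — the exact null
needed for calibration tests. Base duration is 10 s at ideal pace.
Subjects vary around their preset by a symmetric amplitude multiplier
1 + N(0, 0.3), floored at 0.2. The multiplier is deliberately symmetric:
with a right-skewed (e.g. lognormal) multiplier, group metric
distributions inherit enough skew that the Shapiro-routed Welch t test —
which small expert groups almost always reach, because Shapiro has no
power at n = 4 — becomes measurably anticonservative, and the null
calibration of the group comparison drifts above nominal. With the
symmetric model the measured type-I rate at the study cohort size
(14 novices / 4 experts) is 5.6% ± 0.4 over 3000 replicate cohorts; the
small residual excess over 5% is the textbook anticonservatism of routing
mildly non-normal tiny samples to a t test, inherent to the procedure
itself.

These defaults put expert normalized metrics at a few × ideal and novice
values several-fold higher at es = 4, the scale structure reported for
real cohorts. What the generator does **not** emulate: anatomical
constraints and collisions, camera-view coupling, tracker dropouts and
ferromagnetic disturbances, fatigue or learning within a session, and
real inter-subject strategy differences. Passing tests therefore show
that the pipeline recovers expertise structure *of the assumed form*
(excess tremor, slowdown, force overshoot) at realistic cohort sizes —
not that it would reach the same accuracy on any particular real cohort.

## Classifiers

Labels: novice = 1, expert = 2 (expert is the positive class everywhere).
Features are z-scored with training-fold statistics by default (the
normalized metrics span two orders of magnitude); standardization makes
SVM and LDA predictions invariant to affine feature rescaling.

- **SVM**: soft-margin linear kernel (C = 1, configurable).
- **KNN**: K = 3 (odd, so binary votes cannot tie); the reported score is
  the expert posterior Ki/K ∈ {0, ⅓, ⅔, 1}.
- **NN**: d→3→1, tanh hidden layer, linear output regressed onto the
  {1, 2} targets. Training is staged Levenberg–Marquardt (damped least
  squares with a bounded evaluation budget per stage) on a 70% split,
  with early stopping on the held-out 30% (patience 5). Small Tikhonov
  residuals (λ = 1e-4) keep the system over-determined — LM requires at
  least as many residuals as parameters, and the 3d + 7 weights of a
  7-input network exceed typical LOSO fold sizes — and bound weight
  growth on separable data. Output below/above [1, 2] is clamped, then
  rounded: raw ≥ 1.5 → expert (round-half-up on the target scale; the
  midpoint convention is documented because it is otherwise arbitrary).
  The N/d hidden-node guideline is enforced as a warning, not an error,
  since the study-sized cohorts (17 training subjects, 7 features)
  intentionally violate it.
- **LDA**: Fisher projection w = S_w⁻¹(μ₂ − μ₁) with the pooled
  within-class covariance ridge-regularized by 1e-6·trace, and the
  decision threshold at the midpoint of the projected class means.

All fits are deterministic given the spec seed (the network's split and
initialization derive from it).

## Validation pipeline

LOSO cross-validation holds out all of one subject's vectors, refits the
classifier (including standardization statistics — no leakage from the
test subject), and assigns the subject by majority vote over their
vectors; a tie (possible only with an even trial count) resolves to
expert, the positive class. Folds that lose an entire class are an error.

Measures, as percentages: accuracy = 100(TP+TN)/total; precision =
100·TP/(TP+FP), recall = 100·TP/(TP+FN), each defined as 0 when its
denominator is 0; F1 is the harmonic mean of precision and recall, 0 when
both are 0 — matching the degenerate all-zero row convention of the
published tables. Display rounding is 2 decimals, half-up. The inverse
map (`confusion_from_measures`) reconstructs integer confusion counts
from printed precision/recall plus cohort sizes; with precision = 0 and
TP = 0 the false-positive count is not identified by precision/recall
alone, so an optional accuracy argument disambiguates — without it that
case raises.

Group comparisons: Shapiro–Wilk per group at α = 0.05 routes to Welch's
two-sided t test (both groups normal) or the two-sided Mann–Whitney U
test; a constant group has undefined normality and routes to
Mann–Whitney with a warning. Welch rather than pooled-variance t because
novice and expert spreads differ by an order of magnitude on these
metrics.

## Problem sizes used by the checks

The refinement-oracle checks compare 20-Hz metrics against 10×-refined
integration on random trajectories with spectral content ≤ 0.5 Hz, where
the discretization deficit is safely below the 1% tolerance (gross tool
motion lives in this band; faster content is the tremor the filter
attenuates anyway). Simulation-based properties run at the study cohort
shape, 14 novices + 4 experts: 100 paired trials for tremor→metric
monotonicity, 20 replicate cohorts for LOSO accuracy, and 1000 (test) /
5000 (acceptance script, for a tighter binomial SE) replicate cohorts for
the null calibration. The measures↔confusion round-trip is exhaustive
over all valid confusion matrices with ≤ 30 subjects (45 880 cases).

## Known limitations

- The energy metrics are effort proxies in reduced units, not calorimetric
  energy; absolute values are meaningless without the normalization.
- Work conflates bending-force magnitude with tip displacement; a signed
  mechanical work would require the force vector, which the sensor does
  not provide.
- The 9.9-Hz effective cutoff means the nominal 12-Hz configuration is
  not literally realizable at 20-Hz sampling; all quantities are defined
  with respect to the clamped filter.
- A single ideal reference trial is a point estimate; normalized metrics
  inherit its trial-to-trial variability. Ratios should be compared
  within, not across, (task, tool) cells.
- Expertise classification is binary; intermediate skill levels are out
  of scope.
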