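# Methods

`gazecal` evaluates how well appearance-based smartphone gaze estimates can
separate fixations on the eyes versus the mouth of a face shown on screen,
and how much per-subject calibration improves that separation. It implements
the full desk-side analysis: task geometries, a synthetic gaze-estimate
generator, two calibration methods, the two error metrics, and the gated
statistical protocol.

## Coordinate system and task geometries

All geometry lives in a canonical top-left-origin screen frame (x rightward,
y downward, cm). Camera-relative predictions can be ingested by declaring the
camera position on the `ScreenLayout`; the two frames differ by a pure
translation, so conversion is exact. The default screen is a 6.2 cm x
11.0 cm portrait rectangle; grid margins, circle centre/radius and the
absolute face placement are layout parameters with defaults fitting that
screen — they are free choices of the protocol, not measured values.

Four tasks, each fixating waypoints for 1.0 s at 30 fps (30 frames per
waypoint):

* **grid** — 4 x 4 calibration grid, 16 waypoints, one pass (480 frames);
* **face_small / face_large** — the visiting sequence mouth, left eye,
  mouth, right eye, repeated 5 times (600 frames). The eye–mouth distance is
  defined as the Euclidean distance from the mouth to the midpoint of the
  two eyes, with the eyes symmetric about the vertical line through the
  mouth; this makes the single scalar separation (3.1 cm small, 4.3 cm
  large) well defined. The inter-eye gap (2.0 / 2.8 cm) is a layout default.
* **circle** — 12 waypoints equally spaced on a circle (radius 2.5 cm,
  centred on the screen midline), one pass (360 frames).

## Synthetic gaze-estimate generator

The generator emulates the structure of errors that appearance-based
predictors show on fixation tasks: per-subject systematic shift and gain,
conserved across that subject's tasks but varying between subjects, plus
frame-level jitter and lost frames. For true target (x, y):

    x_hat = scale_x * x + bias_x + nonlin_x * x^2 + eps_x,  eps_x ~ N(0, sd_x)

and analogously in y. Blinks and segmentation failures are independent
Bernoulli events per frame; flagged frames carry no prediction. The optional
quadratic term (default 0) exists solely to exercise the linear-vs-SVR
comparison in a regime where the linear model is misspecified. Per-subject
randomness derives from the cohort seed through `SeedSequence.spawn`, so any
subject is reproducible in isolation and a whole cohort is bit-reproducible.

Cohort defaults (the study conditions used by the tests, the analysis
scripts and `scripts/acceptance.py`):

| parameter | default | rationale |
|---|---|---|
| n_subjects | 16 | analysable cohort size of the evaluation design |
| bias sd | 2.5 cm per axis | shifts of a substantial fraction of the screen, large enough that the uncorrected small-face misclassification of the reference cohort falls in the 0.25–0.40 band the evaluation design targets |
| scale sigma | 0.15 (lognormal) | visible per-subject stretch/contraction with gains straddling 1 |
| fixation jitter sd | 1.6 cm per axis | puts the post-calibration small-face rate near the analytic two-landmark value Phi(−3.1/(2·1.6)) ≈ 0.17, the regime the method comparison probes |
| dropout | 0.253 | the observed 74.7% face/eye-segmentation success rate |
| blink | 0.02 | a small per-frame blink probability at 30 fps |

What the generator does **not** model: temporal autocorrelation, saccade
dynamics and pursuit lag (fixations are scored frame-wise), manual frame
reallocation (`excluded_manual` is schema-only), lighting, head pose,
phone-distance and roll-angle effects. Passing tests therefore demonstrate
correctness of the analysis machinery and the qualitative behaviour of the
methods under the modelled error structure — not field accuracy of any gaze
predictor.

## Calibration

**Moment matching (linear).** Per axis, with truth moments (mu, sigma^2) and
prediction moments (mu_hat, sigma_hat^2) on the calibration grid:

    a = sqrt(sigma^2 / sigma_hat^2),   b = mu − a · mu_hat,
    corrected = a · x_hat + b.

This is the unique positive-gain affine map under which corrected
predictions share the truth set's centroid and per-axis variance. Variances
use the population convention (divide by n); the ratio is
convention-invariant when both sides use the same convention, so the choice
only pins down bit-level reproducibility. Per-axis variance matching is the
implemented reading of "preserving variance about the centroid", consistent
with the closed form above; radial-distance variance matching would be a
different (non-separable) transform. Degenerate prediction variance raises
an error instead of silently falling back to translation-only, which would
corrupt the method comparison. Because the gain is a square root it is
always positive: mirror-image corruptions are provably not corrected, and
the test suite asserts that limitation. On noisy data the fitted gain is
typically below 1/scale, because jitter inflates prediction variance and
moment matching matches total variance — a property of the method itself,
not an implementation artefact.

**SVR comparator.** One epsilon-insensitive RBF support-vector regressor per
output axis, fitted on the same grid frames after unit-variance feature
standardisation (C = 1, epsilon = 0.1, gamma scaled by feature variance —
the common reference defaults; none are tuned). The original formulation of
this comparator regresses from a CNN's penultimate-layer features; those
require running the network, so the feature vector here is the predicted
point itself, optionally extended with its quadratic terms. This preserves
the method's form — nonlinear regression from prediction-derived features to
truth — and is a declared deviation: absolute SVR numbers are not comparable
to any CNN-feature implementation, only the linear-vs-SVR contrast under the
shared synthetic conditions is meaningful.

Both methods are always fitted per subject, on that subject's valid
calibration-grid frames only, then applied to the other tasks.

## Error metrics

**Face tasks.** Each valid frame's prediction is assigned to the nearest
facial landmark by Euclidean distance. Under the default `eyes_vs_mouth`
grouping the two eyes collapse into one class before comparison (the
endpoint is eye-region versus mouth separation; whether left/right eye
confusions were counted as errors is not decidable from the protocol, so a
`three_way` mode is exposed for sensitivity analysis). The score is the
per-subject proportion of misclassified valid frames. Nearest-landmark ties
break by the fixed order left eye, right eye, mouth — a measure-zero event
under continuous noise, pinned for determinism.

**Circle task.** Per-subject mean Euclidean error in cm, two variants:
`to_outline` (headline) measures |dist(prediction, centre) − radius|, the
distance to the nearest point of the circle; `to_waypoint` measures distance
to the scheduled waypoint and is frame-wise never smaller. `to_outline` is
invariant to rotations of the predictions about the centre; `to_waypoint` is
not.

## Statistical protocol

Per-subject metric vectors are compared pairwise with a normality-gated
paired test: Shapiro–Wilk on **both samples** at 0.05 selects a paired
t-test (both pass) or an exact Wilcoxon signed-rank test. Gating on the
samples rather than on the paired differences follows the evaluation
protocol being reproduced; the textbook alternative (gate on differences)
is deliberately not used. Zero differences are dropped before ranking; an
all-zero difference vector is a degenerate comparison and raises.

Robustness is assessed with a classical Levene test (group-mean centring,
chosen because no median-centred variant was specified) of the
pre-calibration vector against the pooled post-calibration sample — the
concatenation of both methods' per-subject values, so the post group has 2n
entries and df = (1, 3n − 2) = (1, 46) at n = 16. All tests are two-sided at
the 0.05 convention; no multiple-testing correction is applied, matching the
protocol.

Monte-Carlo checks: under a Gaussian null the gated procedure's type-I error
at nominal 0.05 stays within ±0.015 over 2,000 replicates, and the Levene
null behaviour is checked distributionally over 500 seeds.

## Problem sizes and numerics

The reference cohort is 16 subjects x 4 tasks (~32,600 frames, ~2 s to
simulate and score); analytic-oracle checks use 10,000 frames per
configuration; moment-matching is verified on 1,000 random fixtures.
Float64 throughout; CSV output uses `%.17g` so coordinates round-trip
exactly; exactness assertions use 1e-9 (method guarantees) and 1e-12
(geometric constructions).

## Known limitations

* The linear model corrects shift and per-axis stretch only: rotations,
  shear, reflections and nonlinear distortions leave residual error.
* The SVR comparator's features differ from CNN-internal features (above).
* The generator's Gaussian, frame-independent noise understates the
  temporal structure of real gaze traces; dropout is independent of gaze
  position, whereas real segmentation failure is not.
* Statistical conclusions at n = 16 inherit the usual small-sample caveats;
  the Shapiro–Wilk gate has low power at that n.
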