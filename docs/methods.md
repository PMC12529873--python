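# Methods

This note documents the models, conventions and numerical choices behind
`fedspine`, and what the synthetic experiments do and do not demonstrate.

## Angle geometry

Coordinates are continuous, 0-based pixel centers with the origin top-left
and y pointing **down** (image convention). Each annotation records which
screen direction is anatomically anterior (`facing`); all angles are
computed in a canonical frame with anterior = +x, so SS, PI and LL are
invariant under horizontal mirroring when `facing` is toggled, while PT
flips sign if an image is mirrored without updating `facing`.

Definitions (Duval-Beaupère conventions):

- `SS`: unsigned acute angle between the sacral endplate line and the
  horizontal. In normal standing anatomy the endplate descends anteriorly,
  so the internal signed slope is positive.
- `PT = atan2(anterior component, vertical component)` of the segment from
  the sacral-plate midpoint M to the bicoxofemoral point H, measured from
  the vertical; positive when M lies posterior to H.
- `PI`: signed angle at M between the caudal perpendicular to the sacral
  endplate and M→H. With these sign conventions the anatomical identity
  PI = PT + SS is an algebraic identity of the implementation (observed
  deviation ~1e-14°); an independent rotate-to-horizontal oracle in the
  test suite confirms the convention, not just the identity.
- `LL`: signed angle between the superior endplate of L1 (default;
  T12 selectable, since the landmark set starts at T12) and the sacral
  endplate, positive for lordotic (posteriorly opening) curvature.

Degenerate geometry (coincident endplate points, H = M) raises an
`InvalidGeometryError` instead of returning NaN: a silent NaN inside a
federated average would poison every client's next round. Angles are kept
in double precision; nothing is rounded inside the library.

The 29-landmark schema is: 6 vertebrae (T12–L5) × 4 body corners, the
anterior/posterior extremes and midpoint of the superior sacral endplate,
and the two femoral head centers. The inclusion filter
(`validate_annotation`) mirrors clinical practice: an image is usable only
when all 29 landmarks are present, finite and inside the field of view.

## Synthetic cohort generator

Real spine radiographs cannot ship with the package, so the generator
replaces them with pseudo-radiographs whose ground truth is exact by
construction. Its purpose is to reproduce the *statistical structure* the
federated comparison depends on, not photographic realism:

- **Unequal centers.** Four profiles with patient shares 0.45/0.35/0.14/0.06
  (largest-remainder apportioning), emulating one large, one medium and two
  small hospitals.
- **Center heterogeneity.** Per-center angle distributions
  (PI ~ N(μ_c, σ_c); PT = PI·f with f ~ N; SS = PI − PT; LL linear in PI
  plus noise) with mean PI spanning 42°–58° — the smallest center is
  "younger": lower mean PI, larger spread. Image appearance also differs per
  center (intensity shift, contrast scale, noise level, occlusion-bar
  probability standing in for instrumentation).
- **Follow-ups.** 3–4 visits per patient; per-visit angles are perturbed by
  ≤ ~2° around the patient baseline, and all of a patient's images stay in
  one split.
- **Exact closure.** `build_landmarks` places the sacral endplate at slope
  SS, H at angle PT from the vertical at a pelvic-thickness distance, and
  stacks vertebral quadrilaterals whose endplate slopes interpolate from the
  sacral plate to the L1 superior plate (pinned at SS − LL). Morphology
  (heights, widths, disc spaces, plate tilts of non-pinned plates) is
  jittered per patient. Landmarks are stored as continuous floats — never
  pixel-quantized — so recomputing the four angles reproduces the requested
  values to ≪ 1e-6°. Anatomy that would leave the canvas is retried at
  ×0.85 scale (deterministically, the jitters being drawn once).

Default canvas is 256×256 at 0.5 mm/px; tests and the desk-scale study use
64×64 at 2 mm/px (the same 128 mm field of view). Everything is a pure
function of (profiles, n_patients, seed).

What the generator does **not** model: true radiographic texture and
projection physics, scoliosis-induced axial rotation, annotation noise
(ground truth is exact), missing landmarks (the inclusion filter is
exercised by construction in tests, not by the generator), and longitudinal
trends in follow-ups. Passing tests therefore demonstrate correctness of
the pipeline and the *relative* behaviour of the training strategies under
controlled heterogeneity — not clinical-grade absolute errors.

## Landmark localizer

A compact encoder–decoder ("hourglass") CNN implemented directly in numpy
with hand-written backpropagation (verified against finite differences to
rel. 1e-4 in float64). Configuration: input size, number of stacks
(reference setting 2; desk preset 1), base channels, heatmap stride (4 by
default, i.e. 16×16 heatmaps for 64×64 input), 29 output heatmaps.

- **DSNT head.** Raw per-landmark maps are softmax-normalized into
  probability distributions; coordinates are their expectation over fixed
  grids (2k − (n+1))/n ∈ (−1, 1), making outputs resolution-independent and
  fully differentiable.
- **Loss.** Mean over batch and landmarks of ‖p − gt‖₂ (normalized units)
  plus a divergence between the predicted heatmap and a Gaussian target
  (σ = 1 heatmap px by default) rendered at the ground truth and
  renormalized to sum 1. The divergence is Jensen–Shannon by default
  (KL selectable); its gradient w.r.t. the predicted map is
  0.5·log(p/m)/count with m the midpoint distribution. With several stacks
  the loss is averaged over per-stack outputs (intermediate supervision);
  the last stack predicts.
- **Optimizer.** Adam (0.9/0.999, ε 1e-8), He-normal initialization, all
  seeded. Reference schedules: LR 1e-4, ×0.1 after 50 epochs (centralized/
  local) or after 15 federated rounds; early stopping after 10 validation
  epochs without improvement (strict comparison with 1e-6 tolerance);
  checkpoint = parameters of the best-validation epoch; batch size 8. The
  validation metric is the mean landmark error in mm (loss selectable).
- **Augmentation** (train-time): CLAHE, coarse dropout, brightness/contrast,
  Gaussian blur, pixel noise, rotations in ±10° — rotation transforms the
  landmarks with the same matrix about the image center; photometric
  transforms leave them untouched. Aspect-preserving resize scales the long
  side, pads with the border-median intensity, and records the affine map so
  predictions can be reported in original pixels.

## Federated protocols

Clients are hospitals; one synchronous round = broadcast → `local_epochs`
local epochs per client → aggregate. The client interface returns only
(parameters, sample count, scalar metrics): no sample object can cross the
server boundary, and a test asserts this. Updates are reduced in sorted
client-id order so results are bit-reproducible. Client optimizer state is
reset each round (standard FedAvg practice).

- **FedAvg**: θ ← Σ (nₖ/Σn)·θₖ.
- **FedOpt**: pseudo-gradient g = θ − avg(θₖ); FedAdam-style moments
  (β = 0.9/0.999, τ = 1e-9, no bias correction), θ ← θ − η·m/(√v + τ).
  A plain-average mode with η = 1 reduces *exactly* to FedAvg (used as an
  equivalence oracle).
- **FedProx**: FedAvg aggregation with client objective + (μ/2)‖θ − θ_g‖²
  (default μ = 0.01, μ = 0 reproduces FedAvg bit-for-bit). The reference
  configuration lists a tiny FedProx "server LR"; standard FedProx
  aggregates by plain weighted average, so that is the default here, with
  an optional server-side damping factor for users who want the literal
  damped interpretation.

Reference schedules: FedAvg 10×30 (300 local epochs/client), FedOpt 3×100
(300), FedProx 10×100 (1000) — reproduced by dry-running the round loop and
reading its counters.

## Desk-scale study

`fedspine.study.run_study(seed)` runs the three-arm comparison end to end:
~120 patients across the four default centers (≈420 images, 64×64 at
2 mm/px), a one-stack 8-channel localizer, shared initialization, patient-
level 80/10/10 split. Schedules: locals 30 epochs; FedAvg 5 local epochs ×
6 rounds (30 total passes); centralized 20 epochs — preserving the
200:300 centralized-to-federated budget proportion of the reference
configuration. All arms share LR 2e-3: the reference 1e-4 is tuned for a
multi-million-parameter model at 768×768 and optimizes far too slowly for
a ~15k-parameter model at 64×64; 2e-3 lets the federated arm approach its
error floor within the six pinned rounds. Augmentation is off in the study
preset (the budget is too small to amortize it). External error for every
arm is averaged over the same ordered (train center, other test center)
pairs, so arms are weighted identically.

Typical outcome (three seeded replicates): hospital-local models fail to
transfer (external angle MAE ≈ 20–40°, and small centers are poor even
internally), FedAvg lands within ~25% of centralized (≈ 7–10° vs ≈ 5–9°),
and in most replicates both findings hold simultaneously. Known residual
variance: with only six aggregation rounds and per-round optimizer resets,
the federated trajectory occasionally settles on a worse plateau for an
unlucky seed — the tests therefore require a majority of replicates, not
all of them.

## Numerical conventions and edge cases

- Normalized-coordinate mapping: pixel x ↦ (2x + 1 − S)/S; its inverse is
  used for reporting; target-heatmap centers use the analogous heatmap-grid
  mapping. Ties in target-heatmap argmax at half-integer centers may fall
  to either neighbour.
- Divergence logs are guarded with 1e-12; 0·log 0 ≔ 0 in KL terms.
- Euclidean-loss gradient at p = gt is defined as 0.
- Apportioning (center shares, split fractions) uses largest-remainder
  rounding, ties broken by position; centers with < 3 patients trigger a
  warning and leave splits empty rather than failing.
- Checkpoint archives are numpy `.npz` files containing parameters, the
  model config and metadata; reload is bit-stable.
- Errors are aggregated per image first, then averaged across images; PCP
  thresholds are inclusive (error = τ counts as correct).

## Limitations

- The localizer is CPU-oriented numpy; the 768×768 two-stack reference
  configuration is expressible but impractical to train here.
- Synthetic angle profiles are plausible rather than calibrated to any real
  per-hospital distribution; absolute error levels should not be compared
  with clinical studies.
- Synchronous, all-clients-every-round participation only; no secure
  aggregation or differential privacy.
- No significance testing between arms; the study reports means, medians
  and PCP only.
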