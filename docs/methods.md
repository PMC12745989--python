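# Methods

## The analysis problem

The pipeline quantifies how image quality interacts with semantic coding
in visual cortex at the level of multi-voxel response patterns, and
whether quality itself can be read out from those patterns. Inputs are
trial-level voxel betas (one amplitude per voxel per stimulus
presentation) for seven bilateral visual areas, plus a trial table
carrying image identity, content category (face / object / scene),
quality level (low / neutral / high, binned from 0–100 mean opinion
scores at 35 and 70), task (quality assessment or content
classification), run, block and timing. The package never estimates
betas from time series; a generative simulator stands at the front of
the chain so every downstream stage is testable end to end.

## Design generation

The design is fully constrained: with the defaults, each task uses
9 category × quality cells × 16 unique images, each presented twice, for
288 trials per task; 8 runs × 4 blocks × 18 trials hold both tasks, with
block order QA-CC-CC-QA on odd runs and CC-QA-QA-CC on even runs. Three
numerical commitments matter:

- **Exact ISI solving.** A block is instruction (4 s) + 18 × 3.5 s
  images + 18 ISIs drawn from {0.5, 2.5, 4.5} s. The ISI multiset is
  found by exact enumeration over rational counts so the block total is
  exactly 96 s (no float accumulation); one feasible multiset is chosen
  uniformly at random and shuffled.
- **Repetition control.** The duplicated image list is ordered by a
  randomized exhaustive backtracking search enforcing at least
  `min_lag` (default 1) intervening trials between the two
  presentations of an image. Infeasible inputs raise; the search cannot
  loop forever because it is exhaustive over a finite space.
- **Shared order.** By default all participants see the same sequence
  (a fixed presentation order); a per-participant switch re-randomizes.

The category-sequence optimization used for event-related efficiency in
real acquisitions is deliberately out of scope: the simulator emits
betas, not BOLD time series, so hemodynamic efficiency has no meaning
here and a constraint-satisfying randomized sequence is the appropriate
replacement.

## Generative model of betas

Per image *i* with category *c* and quality *q*, a 3-dimensional latent
is drawn once and shared by both presentations:

    z_i = s · e_c + ε_i,          ε_i ~ N(0, σ_lat² I)

with semantic effect `s` (default 1.0) and shared exemplar variability
`σ_lat` (default 0.5). Each ROI adds its own exemplar component
`ε_i^roi ~ N(0, σ_roi² I)` (default σ_roi = 0.35), so different areas
carry partially independent evidence about the same image.

- **Low-level areas** (calcarine, cuneus, lingual, superior occipital):
  `code = g(roi, q) · (z_i + ε_i^roi)` with gains rising with quality
  (defaults 0.2 / 0.5 / 0.9) — degraded images carry less semantic
  signal.
- **High-level areas** (middle occipital, inferior occipital, fusiform):
  `code = M_{roi,q} (z_i − s e_c) + g_hi · s · e_c + ε_i^roi` with
  constant gain `g_hi = 0.8` — semantic strength is quality-invariant
  (the compensation effect). Only the non-semantic residual passes
  through the mixing transform `M_{roi,q}` (a random rotation, drawn per
  high-level ROI, and per quality iff `quality_dependent_mixing`), which
  is what makes the low-to-high mapping vary with quality without
  touching within-quality category geometry. Routing the full latent
  through `M` instead would rotate the category means differently per
  quality and spuriously modulate high-level semantic content — the
  main subtlety in the generator's design.

Voxel betas are `A_roi,hemi · code` on a designated subset of reliable
voxels (default 100 of 150 per unilateral ROI; loading rows normalized
to unit power so designated-reliable voxels are genuinely responsive)
plus two i.i.d. Gaussian noise channels per presentation (`noise_sd`,
`repetition_noise_sd`, defaults 0.6 each, adding in quadrature).
Unreliable voxels receive pure noise. Finally a quality-specific mean
pattern `b_{roi,hemi,q} ~ N(0, σ_bias² I)` (default σ_bias = 0.2) is
added over the reliable voxels of every same-quality trial — the
multivariate counterpart of univariate activation differences between
quality levels. Because it shifts all same-quality patterns identically
it leaves within-quality representational geometry essentially intact
(whole-RDM quality information content stays at ~0.05–0.15, i.e. no
explicit quality code), yet it gives every area a weak, independent
quality signature, which is what makes quality decodable from pattern
combinations and the all-ROI joint decoder the strongest.

With these defaults the synthetic noise ceilings (mean correlation
between the two repetition patterns of an image) land around 0.2–0.4,
in the range typical of event-related visual fMRI.

What the generator does **not** emulate: BOLD dynamics and autocorrelated
scanner noise, motion and physiological artifacts, voxel geometry and
spatial smoothness, between-participant anatomical variability, and
task-dependent attentional modulation. Passing recovery tests therefore
demonstrates that the analysis chain is correct and well calibrated on
data satisfying its assumptions — not that real data satisfy them.

## Pattern extraction

Per unilateral ROI: trials are averaged into 18 condition means
(2 tasks × 3 categories × 3 qualities) per run; runs are split into odd
and even halves and averaged within each half; each voxel's reliability
is the Pearson correlation between its two 18-point profiles
(zero-variance profiles are flagged undefined and rank last). The top
k = 100 voxels per unilateral ROI are selected (ties broken toward the
lower voxel index, deterministically), left- and right-hemisphere
selections are concatenated (left first), and per-image patterns are
kept per repetition and as the repetition average. Every pattern is
z-scored across its 2k entries (population SD; idempotent). Z-scoring
is applied to per-repetition vectors with the same rule as averaged
vectors so cross-prediction and noise ceilings operate on comparable
objects.

## RSA

ROI RDMs use correlation distance (1 − Pearson r between patterns).
Ideal RDMs: categories as orthogonal one-hot vectors (correlation
distance 0 within, 1.5 between, since r of distinct one-hots is −1/2);
qualities as 2-d codes low (0,1), neutral (1,1), high (1,0) under
Euclidean distance (neutral is 1 from both extremes, low–high is √2).
Information content is the Pearson correlation (Spearman available)
between strictly-upper triangles; per-quality semantic content is
computed on the sub-RDM of that quality's images, which is the only
construction that yields a per-quality value from a single RDM.
Undefined correlations (constant triangles) propagate as flagged NaN,
never as 0. Group analyses use Welch's heteroscedastic ANOVA with the
Welch–Satterthwaite denominator df and Games–Howell pairwise tests on
the studentized-range distribution; both are implemented directly from
the textbook formulas (scipy provides the reference distributions) so
Monte-Carlo calibration suites run in seconds, and both are verified
against pingouin and hand-evaluated formulas in the tests.

## Inter-ROI mapping

One ε-insensitive SVR (RBF kernel, C = 1, ε = 0.1, scikit-learn) per
target dimension, inputs standardized on the training fold only.
Cross-prediction: a model from source repetition 1 to target repetition
2 and a second model in the reverse pairing; each held-out image is
scored in both directions by the Pearson correlation between actual and
predicted 200-vectors, and scores are averaged per image then over
images (per-image scoring is the faithful reading of a per-vector
correlation; concatenated scoring is not used). Quality-conditional
generalization trains on three folds of one quality and tests the
held-out fold index of all three qualities, so no test image ever
appears in training; folds are stratified by content category within
quality to avoid category-empty folds at desk scale (a pure-random
switch exists). Seeding fans out from one master seed to independent
streams per (participant, repeat). The noise ceiling averages per-image
repetition correlations per participant and ROI, then over participants;
images with constant patterns are excluded and counted.

## Quality decoding

Features are the repetition-averaged z-scored vectors, concatenated over
the ROI set (200·|set| dimensions at full scale). One RBF-SVR (C = 1,
ε = 0.1) per training fold regresses the integer targets 1/2/3;
out-of-fold predictions are scored with SRCC and PLCC and averaged over
repeats. SRCC uses mid-rank (tied-rank Pearson) handling because the
integer targets are heavily tied; on untied data this equals the
classical 1 − 6Σd²/(n(n²−1)) formula. The group prediction averages
predicted scores per image across participants before scoring (never
averaging correlations). Each ROI set is compared with the all-ROI
joint model by a two-tailed Welch t-test on participant-level means
under Benjamini–Hochberg FDR at q = 0.1; sets that survive are
significantly different, the rest are flagged as matching the joint
model. The random baseline draws continuous uniform scores on [1, 3]
(integer draws available as an option).

## Desk-scale defaults for simulation studies

Full-scale settings (16 images/cell, 150 voxels, k = 100, 4 folds × 10
repeats, 14 participants) are the package defaults. The test and
example suites run a reduced configuration chosen once for the
simulation studies: 4 images per cell (24 images per quality; 4
stratified folds of 6), 30 voxels per unilateral ROI with 15 reliable
and k = 10 (20-dimensional patterns), 2 CV repeats, and 4–14
participants depending on the question. Two dedicated study conditions
are used by the recovery experiments:

- **Semantic-grading recovery:** generator defaults (graded low-level
  gains 0.2/0.5/0.9, constant high-level gain 0.8), 14 participants.
- **Mapping-transform recovery:** flat gains (0.7 everywhere),
  σ_bias = 0, σ_roi = 0, σ_lat = 0.75, with `quality_dependent_mixing`
  toggled. This isolates the inter-areal transform: with graded gains
  the source-area signal-to-noise ratio varies with quality and would
  confound the null arm, so the quality-independent-mixing control is
  only well posed at flat gains.

## Known limitations

- The SVR stage dominates runtime; full-scale 7×7 ROI grids with
  10 repeats are hours of CPU, which is why the simulation studies run
  at the reduced configuration above.
- Welch ANOVA requires nonzero within-group variance; degenerate groups
  raise rather than returning approximate results.
- The exhaustive backtracking shuffle is exponential in the worst case;
  it is instant at experimental scales but not suitable for adversarial
  inputs.
- The generator's latent space is 3-dimensional (one axis per
  category); real category manifolds are higher-dimensional, so
  absolute information-content values are not comparable to real data,
  only their ordering and quality dependence.
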