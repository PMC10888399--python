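# Methods

## The measurement and the question

FLIO records, for every pixel of a 30° × 30° macular field (256 × 256),
the amplitude-weighted mean fluorescence lifetime τ_m (picoseconds, from
an upstream biexponential decay fit) and the photon-count intensity, in
two spectral channels: SSC (498–560 nm) and LSC (560–720 nm). The
question the pipeline answers is whether a binary subject-level label
(here: smoking status) can be predicted from these maps when no change
is visible to a reader — a small-data classification problem with ~50
subjects and two correlated samples (eyes) per subject.

## ETDRS sectorization

The grid is the standard macular ETDRS layout: central disc of 1 mm
diameter, inner ring to 3 mm, outer ring to 6 mm, rings split into
nasal/superior/temporal/inferior quadrants along the ±45° diagonals.
Conversion from degrees to retina uses the emmetropic approximation
0.3 mm/degree (a config field, not a constant), so the FLIO pixel pitch
is 9.0 mm / 256 px and the ring radii are 14.2 / 42.7 / 85.3 px. The
fovea is taken as the image center (the fixation target), so no
registration is performed.

Numerical conventions:

- Ring membership uses half-open radius intervals (lo, hi] in mm.
- Quadrant boundaries: pixels exactly on a diagonal (|dx| = |dy|, which
  occurs exactly because the center of an even-sized image lies on
  half-integer coordinates) are assigned to the vertical quadrant (S
  above, I below). This tie-break is symmetric under horizontal
  mirroring, which makes two properties hold *exactly* rather than
  approximately: OD and OS geometries differ only by the N↔T labels, and
  extracting from an OS image equals extracting from its mirrored image
  with OD geometry. A chiral tie-break (e.g. "clockwise-following
  quadrant") cannot satisfy either exactly.
- Nasal/temporal orientation: OD temporal = image left (configurable;
  a misassignment relabels N↔T features but cannot silently change any
  rotation-symmetric result).
- Sector means are missing-aware (NaN pixels excluded; an all-missing
  sector yields NaN, later imputed with training-fold means inside the
  classifier). How invalid low-photon pixels were handled in the original
  exports is unknown; missing-awareness is this package's choice.

The 36-feature vector is ordered quantity-major:
{τ_m, intensity} × {SSC, LSC} × {C, N1, S1, T1, I1, N2, S2, T2, I2}.

## Feature selection

The `ttest_top3` subset ranks the 18 τ_m features with the classic
pooled-variance two-sample t-test (two-sided p, n₁+n₂−2 df; ties in p
broken by |t|, then canonical order) and keeps the three most
significant. Two scopes are supported and labeled in every output:
whole-dataset selection (how the original study describes it — optimistic
because the test set influences the ranking) and the default leakage-safe
mode, which recomputes the ranking inside every training fold. Whether
the original analysis treated the two eyes of a subject as independent
t-test samples is unstated; both-eyes-as-samples is the default here.

## Classification protocol

- RBF-kernel SVM, C = 1, γ by the "scale" rule, per-feature z-scoring
  fitted on training rows only. None of these are stated for the original
  analysis; they are the de-facto defaults and are config-exposed and
  echoed into every result. No class weighting by default (the heavy
  experiment is left imbalanced at 26 vs 14 subjects, apparently matching
  the original protocol); a class-weight option exists.
- Folding: subjects are stratified by the three-level status
  (non/light/heavy), shuffled per repeat, dealt round-robin into k = 5
  folds, and fold identities are then permuted so no fold is
  systematically largest. All eyes of a subject share the fold. For the
  26/14/14 design this gives fold sizes {12, 11, 11, 11, 9} in every
  repeat.
- The heavy-smoker experiment drops light smokers' rows first
  (52 + 28 = 80 eyes).
- Aggregation: within a repeat, TP/FN/FP/TN are summed over the 5 folds
  (each sample predicted exactly once), then averaged over the 20
  repeats. This order is inferred from the published tables (fractional
  mean cells whose marginals are exact integers) and is asserted per
  repeat. Rates: TPR = TP/(TP+FN), FPR = FP/(FP+TN), accuracy =
  (TP+TN)/total, printed as percentages with two decimals, half-up.
- The ± columns are sample SDs (ddof = 1) over the 20 per-repeat
  percentages; the original tables do not define their ± semantics, so
  this is an explicit interpretation.

## OCT-A encodings

- Histogram: raw counts of the 256 pixel values (all slabs share the
  pixel count, so normalization would not change comparisons; an option
  exists).
- Sectorization: the same 9-sector grid applied to the 20° / 512 px
  field; at 0.3 mm/deg the field spans exactly 6.0 mm, so the outer
  circle inscribes the image (outer radius = 256 px). "Adjusted to fit
  the region of measurement" is ambiguous between inscribing and
  rescaling ring ratios; inscribing is chosen and configurable.
- Local fractal dimension: the slab is binarized globally (Otsu by
  default), and for each pixel the box-counting dimension of its
  window (default 25 px, odd) is the least-squares slope of log N(s)
  vs log(1/s) over box sizes {2, 3, 4, 6, 8, 12}; boxes are anchored at
  the window corner with partial boxes at the edges; borders are
  reflection-padded; an empty window gives 0 and values are clipped to
  the theoretical [0, 2]. The published analysis delegates the method to
  its source without printing parameters, so all of these are exposed
  defaults. The sliding-window implementation is vectorized with
  integral images and is tested for exact equality against the
  per-window loop.
- PCA to the 15 most variable dimensions (sign-fixed so each component's
  largest loading is positive), then t-SNE to 2-D (perplexity 30,
  auto-reduced below n/3; PCA initialization; fixed seed — hyperparameters
  are unstated in the original work and chosen for determinism).
  Group summaries are per-group means and per-axis SDs.
- The pretrained-CNN encoding of the original study requires downloaded
  weights and is represented by a pluggable `external_encoder` hook
  rather than an implementation.

## Synthetic cohort

The generator emulates the study design so the pipeline can be tested
end to end (the clinical data are not deposited): 26 non-smokers,
14 light smokers (cumulative packs in (500, 2500]), 14 heavy smokers
((2500, 8000]), two eyes each → 108 FLIO samples; one light smoker's
OCT-A is dropped (106 samples), mirroring the study's single excluded
angiography dataset.

Lifetime model per channel:
baseline (SSC 240 ps, LSC 280 ps — placing pixels in the familiar
190–350 ps display range) + subject offset (N(0, 12 ps), shared by both
eyes — the only source of within-subject correlation, so eyes are
"similar but not identical") + a smooth per-eye spatial field (white
noise blurred at 8 px, rescaled to 10 ps SD) + per-pixel eye noise
(4 ps) + the group effect. The effect is linear in dose with saturation:
d = min(packs/5000, 1), adding d·(+15 ps) inside the 0.5–1.5 mm annulus
of the SSC and d·(−15 ps) inside the 1.5–3.0 mm annulus of the LSC. The
annuli are computed in retinal-mm coordinates with independent code, not
with the extractor's masks, so extractor bugs remain detectable. The
true per-sector differences in ps are not published; these magnitudes
are stand-ins giving heavy smokers a sector-level standardized
difference of roughly 1, large enough that the qualitative subset
ordering of the published experiments (τ_m informative, intensity at
chance, IR-SSC+OR-LSC ≫ swapped) is recovered. Intensity is i.i.d.
pixel noise (mean 300, SD 60 counts) with no subject or group term.
A foveal τ_m dip hook exists but is off by default (irrelevant to class
separation; keeps the null clean).

OCT-A slabs are stochastic branching vessel trees: biased random walks
from border seed points with branching and stroke widths 1–4 px, stamped
until the target foreground density (default 0.12) is reached, then
blurred and quantized to 8-bit. Density can optionally depend on dose
(`octa_effect`); the default 0 reproduces the negative OCT-A finding.
Default generated slabs are SVC and DCP (the two slabs the analyses
use); all 15 canonical names are accepted.

What the synthetic cohort does **not** emulate: real retinal anatomy
(vessel shadows, macular pigment, optic disc), fluorophore-specific
channel correlations, device artifacts, or realistic OCT-A texture.
Passing tests therefore demonstrate the correctness and calibration of
the *pipeline* (no subject leakage, chance-level behaviour on null data,
recovery of effects placed where the published analysis found them), not
clinical performance; absolute synthetic accuracies are higher than the
published ones because the injected effect is cleaner than biology.

Randomness: every stream derives from numpy `SeedSequence([seed,
subject, eye, stream])` feeding PCG64, so cohorts are bit-identical
across platforms for a given configuration.

## Problem sizes in the test suite

Oracle-equivalence and generator-property tests run on reduced images
(32–96 px) where the check is size-independent; design-level checks
(counts, fold arithmetic, null calibration over 5 cohort seeds,
signal-recovery ordering over 10 cohort seeds with the full 20×5 CV) run
at the full 256 px / 54-subject design. The acceptance script uses one
full-design cohort per quantity.

## Known limitations

- The center-of-image fovea assumption ignores fixation error; no
  registration or fovea detection is attempted.
- The mm/degree conversion is an emmetropic approximation; axial-length
  correction is out of scope (it rescales rings for all subjects alike).
- Single-component lifetime parameters (τ₁, τ₂, α₁, α₂) and raw decay
  fitting are out of scope; the pipeline starts from exported τ_m and
  intensity matrices.
- t-SNE group ellipses are descriptive, not inferential; no permutation
  test is attached to the embeddings by default.
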