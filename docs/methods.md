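# Methods

## Stain model

Bright-field chromogenic IHC obeys the Beer–Lambert law: the optical
density od = −log₁₀(I/I₀) of a pixel is (to good approximation) a linear
mix of per-stain absorbances.  `dabquant` uses a 3×3 stain matrix whose
rows are unit od vectors for hematoxylin (0.650, 0.704, 0.286), DAB
(0.269, 0.568, 0.778) — the standard Ruifrok–Johnston H-DAB basis — and a
residual channel set to their normalized cross product (0.638, −0.710,
0.298).  The residual deliberately has a negative component; it is a
mathematical complement used to absorb off-model color, not a physical
dye, so the non-negativity requirement applies only to the two dye
vectors.  The basis is overridable in `StainModel`/`RunConfig` for labs
that estimate their own vectors.

The od transform is od = −log₁₀((rgb + ε)/I₀) with ε = 1 (finite at
rgb = 0) and I₀ = 255 by default.  Deconvolution solves od = c·M per pixel
with the matrix inverse and clips negative concentrations to zero.
`forward_mix` inverts the pipeline for synthesis:
rgb = round(I₀·10^(−c·M)) clipped to [0, 255].

**Quantization accuracy.** 8-bit rounding limits how well deconvolution
can invert the forward model: one grey level at transmitted intensity x
corresponds to ≈ 0.4343/x in od, so the round-trip error grows roughly
exponentially with total absorbance.  Measured on a (hematoxylin, DAB) od
grid, the max round-trip error is ≈ 0.005 for stain od ≤ 0.5, ≈ 0.02 at
od ≤ 0.8, ≈ 0.03 at od ≤ 1.0 and ≈ 0.10 at od ≤ 1.5 (where combined
channel od reaches 1.9 and only ~3 grey levels remain).  The additive
ε = 1 also contributes a small darkward bias (≈ 0.4343/rgb per channel).
Typical nuclei sit well inside the accurate regime (hematoxylin od
0.45–0.70, DAB od ≤ 0.5 in the synthetic model), and the per-nucleus mean
further averages pixel-level rounding noise.  The property test pins the
0.022 bound at od ≤ 0.8.

## DAB scale and the μ statistic

The normalized DAB map is clip(dab_od / od_reference, 0, 1) with
od_reference = 1.0: a DAB od of 1.0 (already a very dark brown) maps to
1.0.  On this scale the per-nucleus inverted mean
μᵢ = 1 − mean(DAB over Ωᵢ) puts unstained, hematoxylin-only nuclei near
1.0 and strongly stained nuclei around 0.8 or lower, which is the scale
the default thresholds (τ₁, τ₂, τ₃) = (0.89, 0.94, 0.975) assume.
Boundary ties belong to the weaker class (μ = τ₁ is Moderate, μ = τ₃ is
Negative); the classifier is total and monotone on [0, 1].  A different
scanner profile changes the effective DAB scale; that is absorbed by
recalibration, not by touching od_reference.

## Threshold calibration

Calibration is an exhaustive search over monotone triples on a regular
grid, default [0.5, 1.0] in steps of 0.005 (101 points, ≈ 1.7·10⁵
triples), chosen so the conventional triple lies exactly on the grid.
Grid points at 0 or ≥ 1 are excluded because thresholds must lie strictly
inside (0, 1).  Per-class cumulative counts of μ below each grid point
turn a triple into a 4×4 confusion matrix in O(1), and all triples are
scored vectorized (well under a second for thousands of nuclei).  The
objective is macro-F1 by default (accuracy built in, arbitrary callables
accepted); classes absent from both truth and prediction contribute F1 = 0
so the 4-class denominator stays fixed.  Ties resolve to the
lexicographically smallest (τ₁, τ₂, τ₃) — note this places a tau at the
closed lower edge of a separating gap when the data allow it, since the
boundary itself classifies correctly under left-closed semantics.  A
calibration set with fewer than two distinct classes is an error.

## Instance-mask postprocessing

Nuclei are 8-connected.  The cleaning pass (defaults: min_area = 20 px,
fill holes, merge fragments) removes labels whose total area is below
min_area (strict inequality: 19 px is removed, 20 px kept), fills
holes per label without claiming pixels of other labels, and treats the
fragments of one input label jointly, so that hole filling can bridge
them into a single object; fragments that remain disconnected become
separate objects (no distance-based merging — conservative and
deterministic).  Final pieces below min_area are filtered as well; this
makes the operation a projection (idempotent) and guarantees that every
output object has area ≥ min_area.  Output labels are renumbered 1..N in
raster-scan order of first pixel occurrence, so equal inputs give equal
outputs byte for byte.

## Fallback segmenter

The built-in segmenter is intentionally classical: combined nuclear
absorbance (hematoxylin + DAB od) is thresholded by Otsu's method (floored
at od 0.1 so blank tiles return empty masks rather than thresholding
noise), the foreground is split by watershed on the negated Euclidean
distance transform with local-maximum seeds (min seed distance 7 px,
matched to the 6–12 px synthetic radii), and the result goes through the
shared postprocessing.  It is deterministic and adequate for
well-separated nuclei; densely packed clinical tissue is better served by
a learned instance segmenter, for which `run_external_segmenter` provides
an adapter (lazy import; a clear optional-dependency error when absent)
that consumes final label rasters and applies the identical
postprocessing.

## Allred scoring

P bins the positive percentage as 0; (0,1); [1,10]; (10,33]; (33,66];
(66,100].  The clinical table prints integer bins ("1–10%", "11–33%",
"34–66%", "≥67%"), which leave real-valued percentages such as 65.79 or
66.08 unassigned; the right-closed implementation above is the unique
simple completion consistent with all 50 reference rows (65.79 → 4,
66.08 → 5, 66.67 → 5).  Whether the 4/5 boundary is > 66 or ≥ 66 cannot
be distinguished from the reference data (no row falls in [66, 66.08));
`> 66` is implemented.  I is the mode of the positive class counts with
ties resolved toward the stronger class (forced by the reference rows
with 16/16 moderate–weak → I = 2 and 19/19 strong–weak → I = 3); the
mode, not any mean intensity, is what reproduces the (1, 1, 2) → I = 1
row.  Zero-nucleus images raise `UndefinedScoreError` instead of scoring
0: an empty ROI is missing evidence, not a negative tumour, and silently
reporting 0 would fabricate a diagnosis.  The pipeline surfaces this as a
report with status "undefined" and CLI exit code 3.

Percentages are computed in full float precision and compared unrounded;
reports print two decimals.  (The reference worked example's 93.18% is
the truncation of 93.18996…%.)

## Synthetic data

The generator emulates exactly what the pipeline needs to be checked
against, no more: elliptical nuclei (radii 6–12 px, random orientation)
placed by rejection sampling with a 2 px spacing margin (or a configured
overlap fraction), constant hematoxylin od per nucleus drawn from
0.45–0.70, a faint background hematoxylin wash (od 0.02), and a
class-specific constant DAB od drawn from bands (Strong 0.20–0.50,
Moderate 0.075–0.092, Weak 0.037–0.052, Negative 0–0.012) sized so the
recovered μ lands strictly inside its class band with margin for
quantization bias.  The guarantee is enforced, not hoped for: after
rendering, the tile is pushed back through the real deconvolution path,
per-nucleus μ is recomputed, and any violator's DAB od is redrawn (up to
100 rounds) before the tile is returned.  A tile therefore doubles as an
exact end-to-end oracle.  All randomness flows from a single integer seed
through one `numpy` generator; identical specs give bit-identical tiles.

What the generator does *not* emulate: od texture within nuclei (optional
Gaussian texture exists but defaults to off so μ stays analytically
predictable), chromatin patterns, touching/overlapping clusters beyond
the overlap-fraction control, stain variation across a slide,
out-of-focus blur, and background DAB wash (available as a parameter to
exercise the low-positivity failure mode).  Passing tests on synthetic
tiles therefore validate the computational contracts — unmixing, μ,
thresholds, scoring, postprocessing — not segmentation robustness on real
tissue.

The count-table generator draws per-ROI class counts from a three-part
mixture — all-negative ROIs, low-positive ROIs (a few weak/moderate
nuclei), strongly positive ROIs (Dirichlet-split positives, strong-heavy)
with weights (0.18, 0.16, 0.66) and totals uniform on 40–280 — matching
the qualitative spread of the 50 reference ROIs (nine all-negative, a
low-positive tail, a strongly positive majority).

## Evaluation metrics

Segmentation metrics are pixel-level on the binary union of instances:
precision, recall, F1 (Dice) and IoU (Jaccard); IoU ≤ F1 always, with
equality only at 0 and 1.  Any 0/0 is defined as 0 with a warning
(conservative: an empty prediction against empty truth does not claim
credit).  Because per-image scores in the literature are sometimes
object-level, a separately named `matched_instance_f1` (greedy one-to-one
matching by descending IoU, acceptance at IoU ≥ 0.5) is provided;
pixel-level is the default everywhere.  Classification is summarised by a
4×4 confusion matrix (rows = truth; order Strong, Moderate, Weak,
Negative) and macro-F1 with the fixed 4-class denominator;
`present_only=True` averages only populated classes for comparability
with summaries computed that way.

## Problem sizes and determinism

The test suite and examples run on 256×256 tiles with 20–32 nuclei,
2,000-point calibration sets and the 50-row reference table — sizes at
which every check is exact or seeded-deterministic and the whole suite
completes in seconds.  All stochastic tests fix their seeds; the pipeline
itself contains no randomness outside the synthetic generator.

## Known limitations

* The fallback segmenter under-segments dense clusters; it exists to make
  the pipeline self-contained, not to compete with learned models.
* The default thresholds assume the od_reference = 1.0 DAB scale and a
  scanner profile similar to the one they were calibrated on; transfer to
  other scanners requires recalibration (the calibration module exists
  precisely for this).
* Stain-vector estimation (Macenko/Vahadane) and cross-slide stain
  normalization are out of scope; the basis is fixed or user-supplied.
* 8-bit quantization bounds deconvolution accuracy at high absorbance
  (see above); od values beyond ≈ 1.5 per channel are effectively
  unrecoverable from 8-bit pixels.
* Whole-slide handling (tiling, SVS/MRXS readers) is out of scope; inputs
  are tiles/ROIs.
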