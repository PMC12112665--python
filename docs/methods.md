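# Methods

This note documents the model implemented by `painface`, the choices
made where the design was genuinely open, and what the synthetic tests
do and do not establish about real data.

## Pipeline and assumptions

The pipeline assumes a *paired* measurement: a neutral reference frame
and an activated frame of the same face, both as dense face-mesh
landmark sets with a fixed index convention (468 points by default).
Input coordinates follow the image-normalized convention (origin
top-left, y down). Before any displacement is measured, each frame is
similarity-normalized to a canonical frame: the two configured
eye-center landmarks are mapped to (±1/2, 0), so the eye line is
horizontal, the interocular distance is 1, and their midpoint is the
origin. Canonicalization is idempotent and invariant under any in-plane
similarity transform of the input (both properties are tested to 1e-12
and 1e-9 respectively); displacements are therefore expressed in
interocular units and comparable across faces and image resolutions.
Out-of-plane pose changes are *not* corrected — the model assumes
near-frontal frames, as does any 2-D displacement analysis.

Activation of action unit *a* at zone point *i* is the Euclidean
displacement between the canonical neutral and activated positions,
using (x, y) only by default (a flag enables 3-D). Displacement maps to
the FACS 0–5 intensity scale linearly: intensity = min(5·d/d_max(a), 5).
AU43 (eye closure) is conventionally binary and is instead thresholded
at 0.5·d_max. Per-zone scalars are the maximum over zone points (the
strongest local activation; mean reduction is available).

## Scores

* PSPI baseline: AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43. The raw
  maximum under the stated ranges (four 0–5 terms minus overlaps plus a
  binary term) is 16, but the conventional scale maximum is 15; a
  `clamp_to_paper_range` flag (default on) caps the score and both
  behaviours are tested. The clamp is a reporting convention, not an
  input truncation.
* Zone-max score Ps: the sum of per-zone maxima over the six
  pain-relevant zones (AU1, AU6, AU9, AU15, AU17, AU44), range 0–30.
* Emotion-weighted score: Ps multiplied by the detected expression's
  pain-correlation constant (0.8–1.7, neutrality 1). Two fusion
  semantics exist because the underlying definitions conflict: a sum of
  Ps·FE_w over all seven expression categories versus a product with
  the single detected label's weight. `hard` mode (the default)
  implements the single-label product; `soft` mode implements the
  faithful sum, Ps·Σ_e p(e)·w_e, which reduces to hard mode for a
  one-hot distribution and is bounded by [min w, max w]·Ps for any
  distribution. Both are documented and tested; neither is silently
  preferred elsewhere in the pipeline.

Pain levels bin a score into six ordinal categories at thresholds
(6, 12, 18, 24, 30) — equal-width bins over the zone-max range,
left-bin-inclusive (a score of exactly 6 is level 1), zero is level 0,
anything above 30 (possible after weighting) caps at level 5. Weighted
scores are binned on the same thresholds so that weighting can move a
frame across levels; the thresholds are config-overridable.

## Expression classifier

The expression is classified from the same AU intensity vector by a
linear score per emotion, a softmax, and an argmax with ties broken in
the canonical label order (happiness, surprise, neutrality, disgust,
fear, anger, sadness). The default weight matrix is a *template
matcher* built from the prototype emotion→AU map shared with the
synthetic generator (happiness {AU6}, surprise {AU1}, neutrality {},
disgust {AU9}, fear {AU1, AU44}, anger {AU44, AU17}, sadness
{AU15, AU17, AU1}): each row puts 1/|prototype| on its prototype AUs
and −0.25 on all others. The normalization makes scores the mean
template activation, comparable across prototypes of different sizes;
without it, any emotion whose prototype is a superset of another's
(fear ⊃ surprise) outscores it on every noisy frame. The penalty makes
off-template activation count against an emotion, which is what
separates nested templates under noise.

A linear score with no intercept cannot distinguish "no activation"
from a tie, so the pipeline applies a neutrality gate before the
argmax: when no AU intensity reaches `neutral_threshold` (default 1.0
on the 0–5 scale, i.e. a fifth of full scale) the frame is labelled
neutral. This reflects the actual semantics of neutrality — absence of
expression — rather than treating it as a seventh template. All seven
noiseless prototypes at full activation are recovered exactly; at noise
σ = 0.01 the classifier stays at roughly 89–95% accuracy on generated
data. This classifier is deliberately transparent and is *not* a
learned expression model; any user-supplied weight matrix with the same
shape can replace it.

## Synthetic face generator

The generator produces what the pipeline consumes — canonical
neutral/activated pairs — with every latent known. A per-seed template
scatters mesh points uniformly over a face-sized box in canonical units
(eye anchors pinned at ±1/2) and fixes a random unit displacement
direction per zone point. An expression frame displaces each activated
zone point by (intensity/5)·d_max along its direction, exactly
inverting the calibration, so noiseless round-trips recover intensities
to machine precision (tested at 1e-9). Emotions are assigned by
stratified largest-remainder allocation (exact counts when n is
divisible by 7), a per-frame amplitude uniform on [0, 5] scales the
prototype pattern, and isotropic Gaussian coordinate noise is added to
the active frame only.

Ground-truth pain follows the model's own emotion-modulation premise:
the true weighted score is w(emotion)·Ps(intensities) and the true
level bins that value, while the face displays the unmodulated
amplitudes. This is precisely the confound the weighted estimator
exists to resolve: an unweighted reading of the displayed activation
misestimates the level on emotive frames, and multiplying by the
detected emotion's weight corrects it. On 700 frames at σ = 0.01 the
weighted zone-max estimator's average exact-level accuracy exceeds the
unweighted one's by a robust margin (roughly 80% vs 65% across seeds);
the evaluation harness recomputes this table on demand rather than
hard-coding any number.

What the generator does **not** emulate: anatomical zone geometry
(points and displacement directions are random, not face-shaped),
correlated landmark jitter from head pose, AU co-activation beyond the
prototype patterns, identity and appearance variation, and detector
failure modes. Passing tests therefore certify the *arithmetic and
logic* of the pipeline — displacement measurement, calibration,
scoring, weighting, binning, evaluation — not performance on real
faces, which additionally depends on detector quality and per-AU
calibration.

## Units, defaults, and numerical choices

| parameter | default | units | rationale |
|---|---|---|---|
| mesh size | 468 | points | standard dense face-mesh topology |
| d_max | 1.0 per AU | interocular units | template full-intensity displacement; makes calibration exactly invertible and lets noise σ read directly as a fraction of full scale (σ = 0.01 ⇒ 1%). Anatomical faces need per-AU values of a few tenths of a unit, supplied by the user's calibration file |
| AU43 threshold | 0.5·d_max | interocular units | halfway criterion for a binary action |
| neutral gate | 1.0 | intensity (0–5) | a fifth of full scale; below it no template is meaningfully active |
| level thresholds | 6, 12, 18, 24, 30 | score units | equal-width bins over the zone-max range |
| noise σ (tests) | 0–0.02 | interocular units | sub-landmark-spacing jitter |
| unsharp radius/amount/threshold | 2 / 1.5 / 3 | px / – / intensity | conventional mild sharpening; neutral contrast/brightness (1.0) |
| preprocess target width | 480 | px | common detector input scale |

Degenerate inputs raise typed errors rather than propagating NaNs:
coincident eye landmarks (no interocular frame), empty zones, missing
calibration entries, out-of-range AU values, non-monotone thresholds.
Softmax subtracts the maximum score before exponentiation (shift
invariance doubles as overflow protection). Ties in classification are
deterministic (canonical order). File outputs print floats with `repr`,
so fixed-seed pipelines are byte-reproducible.

## Problem sizes used in the shipped checks

The test suite and examples run entirely on generated data: datasets of
70 frames for round-trip and stratification checks, 700 frames at
σ = 0.01 for the estimator comparison, 60-frame temporal series, and
brute-force metric oracles up to 200 items. The full suite completes in
a few seconds on one CPU.

## Known limitations

* The zone index lists, while following the standard mesh convention,
  are one reasonable assignment among many; results on real data depend
  on them and they are deliberately configuration, not code.
* The noise floor of the zone-max score is positively biased (a sum of
  per-zone maxima of non-negative displacement noise), so a truly
  neutral noisy frame never scores exactly level 0; at the default
  scale the floor is ≈0.6 score units at σ = 0.01. Per-subject baseline
  calibration would remove it and is left to deployments.
* Hard-mode weighting is discontinuous at classification boundaries;
  soft mode is the smooth alternative.
* No temporal smoothing: frames are scored independently, which is
  faithful to the per-frame definition of the scores but noisier than a
  tracker on video.
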