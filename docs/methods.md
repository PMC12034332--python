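# Methods

## The procedure

`segqa` treats a software update as an intervention on a fixed patient
cohort: the same CT images are segmented by the pre-update and post-update
versions, so every organ yields a *paired* comparison on an identical voxel
grid. The method has two stages.

**Stage 1 — screening.** For each patient × organ, the two versions'
binary masks are compared with DSC, maximum Hausdorff distance (HD) and
mean distance to agreement (MDTA). A criteria set supplies one threshold
per index; failing *any single* index marks the contour as notably
modified. Two criteria sets ship:

| set | DSC min | MDTA max | HD max | reading |
|---|---|---|---|---|
| A (strict) | 0.99 | 0.05 cm | 0.2 cm | "was the contour touched at all?" — 0.2 cm is one slice at the 2.0 mm protocol |
| B (standard) | 0.9 | 0.2 cm | 1.0 cm | conventional "nearly identical" thresholds |

Because the comparison is version-vs-version rather than version-vs-expert,
an unchanged organ scores exactly (1, 0, 0) and the strict thresholds are
meaningful; comparing each version to expert contours first would hide
update-induced changes inside inter-observer variability.

**Stage 2 — evaluation.** Only flagged organs are re-measured against
expert ground-truth contours, and the per-organ, per-metric paired
difference between versions is tested with the two-sided Wilcoxon
signed-rank test. Two-sided always: updates both improve and degrade
contours, and the screening question is "did it change", not "did it
improve". No multiple-testing correction is applied by default (raw
per-test p-values are the output, with a Holm option available), matching
how such per-organ tables are conventionally reported.

## Geometric definitions and numerical choices

* All internal lengths are millimetres; user-facing criteria and crop
  margins are configured in centimetres and converted exactly once at
  parse time. Human-readable summary tables render distances in cm.
* **Surfaces** are the centers of mask voxels 6-face-adjacent to a false or
  out-of-volume voxel. HD and MDTA are point-cloud distances between these
  centers. This dialect is deterministic and directly checkable against an
  all-pairs O(n²) computation (the test suite asserts bit-exact agreement);
  it is one of several reasonable conventions (signed distance fields and
  mesh distances are others) and treatment-planning systems do not publish
  theirs, so agreement with any particular vendor is *not* claimed.
* **MDTA** is the pooled symmetric average: one division by |∂A| + |∂B|,
  not the mean of the two directed averages. The directed variant is a
  one-line change isolated inside `mean_distance_to_agreement`.
* **HD** is the true maximum, not a percentile: a one-slice threshold only
  makes sense for the maximum.
* **Rasterization** uses the even-odd rule on voxel centers with a
  half-open edge convention (left/bottom inclusive), so an axis-aligned
  rectangle through voxel-center lines covers exactly width × height
  voxels. Contour rings attach to the nearest slice plane; an exact
  half-spacing tie goes to the lower-index slice (RT-Struct planes normally
  coincide with CT planes, so the tie-break only affects adversarial
  input). Rings outside the grid's z extent are errors, not clipped.
* **Threshold semantics**: a value exactly at a threshold does not violate
  (criteria are written as target values, so violation is strict
  inequality). Consequence worth knowing: a one-slice extension on a 2.0 mm
  grid yields HD = 2.0 mm = the criteria-A HD threshold, so such contours
  are caught by their DSC/MDTA, not by HD.
* **Empty masks** make the distance metrics undefined; the pair is reported
  with status `undefined_empty` and always flags (a vanished organ is the
  severest modification). No infinite or sentinel distances are invented.
* **Geometry discipline**: masks compared must share one grid; mismatched
  geometries raise instead of resampling silently. Only constant slice
  spacing is supported.
* **Wilcoxon**: zero differences are dropped before ranking by default
  (classic test; version-identical contours make zeros common and the
  policy is echoed in the report), with the zero-inclusive Pratt variant as
  an option. The exact null distribution is used when the effective n ≤ 25
  with no tied |difference| ranks, otherwise the tie-corrected normal
  approximation. All differences zero → p = 1. The p-value is invariant
  under transforms that preserve the signs and the rank order of the
  |differences| (any increasing affine map); a nonlinear monotone transform
  can reorder |differences| and legitimately change p, so no stronger
  invariance is asserted or tested.

## The anchored rectum crop

Superior/inferior rectal extent varies between observers, so before any
comparison the rectum is limited to `[prostate_zmin − 1 cm, prostate_zmax +
1 cm]`. Design choices, both configurable: the window derives from **one**
designated version's prostate (ground truth when present, else the
pre-update version) and is applied identically to every version — a
per-version window would confound the version comparison; and the window is
closed, so a 1 cm margin on 2.0 mm slices keeps exactly five slices per
side. Cropping is idempotent and never adds voxels; a target emptied by the
crop is returned empty (and then flags as `undefined_empty` downstream).

## Aggregation to organ level

Per-patient verdicts are always produced. The organ-level flag defaults to
the **mean** triple across patients violating the criteria (the reading
used in per-organ bar summaries); `per_patient` mode flags when any single
patient violates, which is the only way to see a worst case — e.g. one
patient's isolated spurious region — that a 25-patient mean dilutes below
threshold. Any patient with an undefined pair forces the organ flag under
both modes.

## The synthetic cohort

The phantom module emulates the *structure* of a version-validation study —
n patients, each with the same named organs in ground-truth, pre-update and
post-update versions — using primitive shapes (spheres, ellipsoids,
axis-aligned tubes, boxes) on a 96 × 96 × 60 grid at (1, 1, 2) mm, i.e. a
2.0 mm slice protocol at pelvic scale. Primitives are deliberate: volumes
and distances are analytic, so every metric has a closed-form or brute-force
oracle. Organ centers get a per-patient uniform jitter (default ±2 mm) from
per-patient child seeds, so cohorts are bit-reproducible under (spec, seed)
and extending the cohort never reshuffles existing patients.

Perturbations mirror observed update failure modes: one-slice terminal
extension; whole-slice truncation; an isolated spurious region at a fixed
offset; carving one organ's overlap out of another (brainstem from brain);
plus translation, dilation and erosion. The "fraction of patients affected"
is realized exactly (round(p·n) patients drawn from a seeded generator). A
perturbation that would change no voxel raises instead of silently
no-opping.

The bundled `scenario_update_failures` cohort (default 25 patients) wires these
into an end-to-end fixture: brain ← carve, lens ×2 and optic nerve ← one-
slice extension, rectum ← 10-slice inferior truncation plus one patient
with an isolated region 4 cm away, bladder ← 1 mm dilation, and four organs
untouched. Its manifest states which organs must and must not flag under
each criteria set (per-organ-mean aggregation), and the pre-update version
is emitted bit-identical to ground truth so the manifest and the
evaluation-stage p-values are deterministic. Small tubular stand-ins are
used for lens/optic nerve so the terminal slice carries the full
cross-section and a one-slice extension has a jitter-independent effect on
DSC.

**What passing these tests does and does not show.** The phantoms have no
CT intensities, no deformable or asymmetric anatomy, no inter-observer
variability in the ground truth, and no spacer devices; organ overlaps are
geometric, not anatomical. Passing demonstrates that the indices, criteria
logic, crop, statistics and reports are computed correctly and
deterministically — not that the criteria themselves have any particular
sensitivity/specificity on clinical contours.

## Problem sizes

Defaults were chosen so a full run is desk-scale: the scenario cohort is 25
patients × 10 organs × 3 versions on the 96 × 96 × 60 grid; the brute-force
metric check uses 200 random mask pairs within 24³ grids; Wilcoxon
calibration uses 2000 simulated 20-pair series. A complete test-suite run
and the acceptance script each finish in well under a minute per stage on a
single CPU.

## Known limitations

* Surface distances are voxel-center point-cloud distances; sub-voxel
  surface positions are not estimated, so all distances are quantized by
  the grid (±1 voxel diagonal at worst, anisotropically for 2 mm slices).
* DICOM RT-Struct is read-only; the canonical write container is the NIfTI
  mask stack with JSON sidecar.
* No image resampling or registration: cross-grid comparisons are rejected.
* Rater variability in ground truth is not modelled; the evaluation stage
  treats expert contours as fixed truth.
* Criteria are fixed thresholds; no ROC-style tuning is provided.
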