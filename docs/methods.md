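# Methods

This note records the models, conventions and numerical choices behind
`cavityqa`, and what its synthetic-data tests do and do not establish about
clinical data.

## Grid and distance conventions

Volumes are 3D arrays in Hounsfield units with axis order (x, y, z), z the
axial slice axis. Voxel indices are 0-based; a voxel's physical position is
its center, `origin + index · spacing` (mm). Every distance in the package —
margins, adjacency, surface distances — is computed in millimetres through
the spacing, never in voxel counts, because clinical margins are metric and
CT grids are anisotropic (in-plane pixels ~1 mm, slices 1.25–2.5 mm). Masks
are stored as uint8 0/1 NIfTI; any nonzero value reads as true. DICOM and
RTSTRUCT input are out of scope; conversion to NIfTI is upstream tooling.

## Visibility metrics

The crop window is the GTV bounding box expanded by `px_xy` voxels per side
in x and y and `px_z` slices per side in z (defaults 10 and 2), clipped to
the volume. The expansion amounts are per-side configuration parameters.
Within the window:

* ROI statistics use GTV voxels with HU < 1000; background statistics use
  non-GTV window voxels with HU < 1000. The bone exclusion applies to both
  sets uniformly so the metric stays defined when a cavity touches the
  skull.
* `contrast = mean(ROI) − mean(background)`; `CNR = contrast / sd(background)`
  with the sample (n−1) standard deviation. When the background SD is zero
  the CNR is reported as undefined (`None`) rather than infinite.
* The low-visibility bands are closed: a case whose metric lies exactly on
  a band endpoint (e.g. contrast = ±10 HU) is excluded. The filter is
  monotone in |contrast| for fixed noise.

The background is defined only by the crop geometry and the bone rule; no
attempt is made to exclude other low-HU structures (e.g. sinus air) beyond
what the crop reaches. The 4-point visual score (fraction of slices on
which the cavity is visible) is a human annotation carried as data; the
package never infers it from images.

## Synthetic head phantoms

The generator emulates the *statistical* structure the visibility and
pre-selection analyses rest on, not anatomy:

* Brain: an ellipsoid at 62 % of each physical dimension, voxel values iid
  Normal(35 HU, σ²) — 35 HU is the standard brain display window level.
  Gaussian iid noise is exact for these analyses because contrast and CNR
  depend only on means and one standard deviation; no reconstruction
  texture or beam hardening is modelled.
* Cavity: one or more balls (default radius 8 mm, a few-mL cavity) with
  mean offset ΔHU from brain; ΔHU is the programmed contrast and is
  negative for the typical fluid-filled hypodense cavity. `n_components=2`
  produces a discontinuous cavity; `in_fossa=False` places it
  supratentorially. Edges are hard by default; `edge_blur_mm` applies a
  Gaussian partial-volume blur to the cavity offset only (skull and air
  stay hard, so no bone HU bleeds into brain tissue).
* Posterior fossa: the inferior-posterior portion of the brain interior;
  brainstem: a vertical cylinder anterior to it. Only containment logic is
  exercised, not anatomical fidelity.
* Skull: a constant 1200 HU shell grown 16 mm outward from the brain by a
  spacing-aware distance transform. The thickness is deliberately larger
  than the crop window's maximum diagonal overshoot beyond the brain
  (√(10² + 10² + 5²) ≈ 15 mm at default crop and spacing), mirroring a real
  head where bone and scalp — not air — border the brain. This matters: if
  the window could reach −1000 HU air, the background mean would be biased
  and measured contrast would no longer estimate ΔHU (an ~18 HU bias at a
  3 mm shell in early experiments).
* Determinism: the seed fully determines the volume; cohort generation
  derives per-case seeds from a master seed via `SeedSequence`, so a cohort
  regenerates byte-identically. Default grid 128×128×64 at 1×1×2.5 mm
  (median clinical slice thickness); multi-phantom analyses use 96×96×48
  with identical spacing, HU levels and cavity size, which changes only the
  amount of background tissue.

Passing tests on these phantoms show that the *estimators and decision
rules* behave as specified under known truth — unbiased contrast recovery,
correct filter decisions, correct geometry. They do not show that real
resection cavities are Gaussian, that real backgrounds are pure brain, or
that any particular clinical cohort would be filtered at the same rates.

## Pre-selection and the 2×2 experiment

* Continuity: exactly one 26-connected component (the most permissive
  standard 3D connectivity; diagonal touches are not discontinuities).
* Location: ≥ 95 % of GTV voxels inside the posterior fossa mask (the
  clinical judgement "located within the posterior fossa" made explicit and
  configurable).
* Removal accounting: a removed case counts against the first criterion it
  fails in the fixed order continuity → location → visibility. Membership
  of the surviving set is order-independent (a case survives iff it passes
  every enabled criterion); only the attribution depends on the order.
* Split: seeded shuffle; training size is `round(0.8·n)` with round half
  away from zero (104 cases give 83/21; an 82/22 split of 104 is not
  reproducible by any plain rounding rule and is not targeted).
* Arms: model 1 trains on the full training split, model 2 on its
  pre-selected subset; each is evaluated on the full test split and its
  pre-selected subset. The pre-selected test set is by construction a
  subset of the full test set, and leakage (a test case in its arm's
  training set) is a hard error.
* The model comparison uses the classical equal-variance two-sample t-test
  on per-case GTV DSC for each test set (Welch available behind a flag);
  two identical constant samples give t = 0, p = 1, while zero pooled
  variance with unequal means is an error. DSC is the primary tested
  metric; HD/MSD/precision/recall are reported descriptively.

## Segmenter slot and the threshold baseline

No neural network is trained or shipped; the trained-model slot is a
contract (`(volume, search_region) -> mask` on the same grid, possibly
empty). The shipped baseline thresholds the image to an HU band inside a
search region (default: the posterior fossa), applies a 1-voxel binary
closing, and keeps the largest 26-connected component if it exceeds
`min_component_mm3` (default 100 mm³). It is a deterministic desk-scale
test vehicle, not a clinical claim.

"Training" an arm means fitting the band from that arm's training cases:
center = median of per-case mean cavity HU, half-width = max(3 × median
per-case cavity SD, 15 HU). The median makes the fit robust to a minority
of zero-contrast cases whose cavities sit at brain HU; the 15 HU floor
keeps the band usable at very low noise. With this model both arms fail on
zero-contrast cavities, which is exactly the mechanism behind the ordering
result: the pre-selected test set's mean DSC exceeds the full test set's
because pre-selection removes the unsegmentable cases from evaluation.

## CTV expansion

Expansion is distance-transform thresholding: CTV = {v : d_GTV(v) ≤ m(v)},
intersected with brain, minus brainstem, unioned with (GTV − brainstem).
When the GTV's nearest approach to the brainstem is ≤ 2 mm (≈ one slice,
the "immediately adjacent" trigger), the allowed margin varies spatially:

    m(v) = 5 + (15 − 5) · min(1, d_bs(v) / 15)   [mm]

i.e. 5 mm at the brainstem surface, linearly recovering to the nominal
15 mm at ≥ 15 mm away. The clinical practice this models is a manual,
planning-system-specific edit; this rule is an explicit, deterministic
stand-in whose two endpoints match the stated margins, not a claim about
any particular clinical construction. If excluding the brainstem would
remove GTV voxels, they are excluded and the overlap volume is logged as a
warning — the conflict is surfaced, never silently resolved.

## Contour metrics

Surface voxels are mask voxels with at least one face-adjacent outside
neighbour (the volume boundary counts as outside). Directed distances run
between surface voxel centers (no sub-voxel meshing, so values are
bit-reproducible); HD is the exact maximum over both directions (a
percentile variant is a configuration choice, not the default) and MSD the
mean of the two directed means. DSC is identically the harmonic mean of
precision and recall on voxel counts. A comparison of two empty masks is
an error — reporting DSC = 1 there would hide segmenter failure — while an
empty prediction against a non-empty reference scores 0 with infinite
surface distances (a recorded total miss). Cohort summaries report mean ±
sample SD and the fraction of cases with DSC > 0.90; a single-case summary
reports SD 0 with a degenerate-n flag.

## Statistical tolerances in the tests

Replicate-phantom recovery asserts that the mean measured contrast over 50
seeded replicates lies within one *single-measurement* standard error,
σ·√(1/n_roi + 1/n_bkg), of the programmed ΔHU. Because the estimator is
unbiased, the mean's own standard error is √50 ≈ 7 times smaller, so this
bound fails with negligible probability while still detecting any
systematic bias larger than a seventh of one measurement's noise. Filter
separation tests use programmed contrasts {−40, −5, 0, 5, 40} at σ = 1 HU:
regimes a comfortable multiple of the sampling noise away from the ±10 HU
band edges, so the keep/exclude decision is deterministic in practice. (A
regime programmed exactly at ±10 HU sits on the closed band's boundary and
its sampled contrast would fall on either side with equal probability — no
deterministic assertion is possible there.)

The expansion-smoothing analysis (CTV DSC > GTV DSC for ≥ 90 % of pairs)
uses blurred-edge phantoms (2 mm) at σ ∈ {4, 8, 12} HU so the baseline
disagrees with the truth at the cavity boundary (GTV DSC ≈ 0.78–0.91, the
regime where margin expansion has disagreement to dilate away); on
hard-edged phantoms the baseline is exact and the comparison degenerates
to equality.

## Known limitations

* Phantom anatomy is schematic; no age-dependent morphology, no MRI.
* The visibility background is whatever the crop reaches minus bone; real
  crops may include CSF spaces or post-surgical air that this package does
  not specially handle.
* The baseline segmenter cannot represent learned spatial priors; results
  about *training-set* curation (as opposed to test-set curation) are
  structural, not quantitative, statements about trained networks.
* The directional margin-reduction rule is one reasonable realization of
  "reduced toward the brainstem"; clinical systems may differ in shape
  between the 5 mm and 15 mm endpoints.
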