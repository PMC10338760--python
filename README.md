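# cavityqa

Quality-assurance tooling for CT-only auto-contouring of the post-surgical
resection cavity in pediatric medulloblastoma radiotherapy.

After resection of a posterior-fossa medulloblastoma, the radiation boost
targets the surgical cavity: the gross tumor volume (GTV) is the cavity
including the tumor–brain interface, and the clinical target volume (CTV)
adds an anatomic margin for subclinical disease. On non-contrast CT the
cavity's visibility varies enormously — blood products, edema and
collapsed cavity walls can make it nearly isodense with brain — which both
degrades auto-segmentation models trained on such data and makes their
evaluation misleading. `cavityqa` implements the computational side of a
visibility-based curation workflow for this problem:

* **Visibility quantification.** Around each GTV a crop window is built by
  expanding the GTV bounding box 10 voxels per side in-plane and 2 slices
  per side along z. With bone excluded by HU thresholding (HU ≥ 1000),

  ```
  contrast = x̄_ROI − x̄_bkg          [HU]
  CNR      = contrast / σ_bkg       [dimensionless]
  ```

  where x̄_ROI is the mean CT number inside the GTV, and x̄_bkg, σ_bkg are
  the mean and sample standard deviation of the surrounding (non-GTV,
  non-bone) voxels in the window. A case is excluded as low-visibility when
  contrast lies in [−10, +10] HU (or CNR in [−0.5, +0.1]).
* **Cohort pre-selection.** Continuity (the GTV is a single 26-connected
  component), location (≥ 95 % of GTV voxels inside the posterior fossa)
  and the visibility filter, with per-criterion removal accounting, a
  seeded 80/20 train/test split, and the four (training set × test set)
  arms of the 2×2 pre-selection experiment.
* **Anatomically constrained CTV expansion.** CTV = GTV expanded 15 mm via
  a spacing-aware Euclidean distance transform, confined to the brain and
  excluding the brainstem; when the GTV is immediately adjacent to the
  brainstem (≤ 2 mm) the local margin is reduced to 5 mm at the brainstem
  surface, recovering linearly to 15 mm at ≥ 15 mm away.
* **Contour metrics.** Dice similarity coefficient (DSC), exact Hausdorff
  distance (HD), mean surface distance (MSD), precision and recall between
  predicted and reference masks, cohort mean ± SD summaries, and the
  independent two-sample t-test (P < 0.05) between model arms.
* **Synthetic head phantoms.** HU-valued CT phantoms (brain at the 35 HU
  window level, skull ≥ 1000 HU, posterior fossa, brainstem) with a cavity
  of programmed contrast ΔHU, noise σ, component count and location — so
  every step above runs end-to-end with known ground truth and no clinical
  data or GPU.
* **Pluggable segmenter.** A deterministic HU-band threshold baseline fills
  the slot a trained network occupies in a clinical deployment; any callable
  `(volume, search_region) -> mask` can be plugged in.

Images and masks are NIfTI (`.nii`/`.nii.gz`, via nibabel); cohorts are
described by a JSON manifest (case id → image and structure paths).

## Worked example

```python
from cavityqa import (PhantomSpec, generate_phantom, compute_visibility_metrics,
                      apply_visibility_filter, expand_gtv_to_ctv, MarginSpec)

case = generate_phantom(PhantomSpec(delta_hu=-40.0, sigma_hu=5.0, seed=7))
m = compute_visibility_metrics(case.image, case.gtv)
print(f"contrast = {m.contrast:.1f} HU   CNR = {m.cnr:.2f}   (n_roi={m.n_roi}, n_bkg={m.n_bkg})")
print("kept by the +/-10 HU contrast filter:", apply_visibility_filter(m, mode='contrast'))
ctv = expand_gtv_to_ctv(case.gtv, case.brain, case.brainstem, MarginSpec())
print(f"GTV {case.gtv.volume_mm3()/1000:.1f} mL -> CTV {ctv.volume_mm3()/1000:.1f} mL")
```

prints

```
contrast = -40.0 HU   CNR = -7.97   (n_roi=856, n_bkg=10845)
kept by the +/-10 HU contrast filter: True
GTV 2.1 mL -> CTV 43.1 mL
```

The measured contrast recovers the programmed −40 HU cavity offset within
sampling noise; the case passes the visibility filter; the 15 mm expansion
grows the 2.1 mL cavity to a 43 mL brain-confined, brainstem-excluding CTV.

## Analysis scripts

Numbered drivers under `analysis/` rerun the study stages on a synthetic
cohort and write tables under `results/` (imaging intermediates go to
`scratch/`):

1. `01_generate_cohort.py` — 30 phantoms mixing high-/zero-contrast,
   discontinuous and supratentorial cavities.
2. `02_visibility_filtering.py` — contrast/CNR per case; filter summary.
3. `03_experiment_matrix.py` — the 2×2 model/test-set experiment with
   per-arm DSC/HD/MSD summaries and t-tests.
4. `04_ctv_expansion_comparison.py` — GTV vs CTV agreement before/after
   identical margin expansion on imperfect prediction/reference pairs.

A `cavityqa` command-line tool exposes the same stages
(`phantom`, `visibility`, `preselect`, `segment`, `ctv`, `metrics`, `run`).

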