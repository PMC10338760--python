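"""Pluggable segmenter contract plus a non-learned threshold baseline.

In the clinical study design this slot is occupied by a trained 3D
segmentation network; no network is trained or shipped here.  The contract
is any callable mapping ``(ScalarVolume, search-region StructureMask) ->
StructureMask`` on the same grid (the output may be empty — a total miss is
a recordable outcome).

The shipped baseline thresholds the image to an HU band inside a search
region (e.g. the posterior fossa), closes 1-voxel gaps, and keeps the
largest 26-connected component if it is big enough.  It is a deterministic
desk-scale test vehicle, not a clinical claim; its HU band must be supplied
(the pipeline fits one from training data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
from scipy import ndimage

from .core import CasePaths, ScalarVolume, StructureMask, read_mask, read_volume, write_mask, voxel_volume_mm3
from .visibility import BONE_HU

__all__ = ["Segmenter", "BaselineSegmenter", "baseline_segment", "fit_hu_band", "run_segmenter_over_cohort"]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class Segmenter(Protocol):
    """Segmenter contract: volume + region of interest -> mask on same grid."""

    name: str

    def __call__(self, volume: ScalarVolume, search_region: StructureMask) -> StructureMask: ...


def baseline_segment(
    volume: ScalarVolume,
    search_region: StructureMask,
    hu_band: tuple[float, float],
    min_component_mm3: float = 100.0,
) -> StructureMask:
    """Threshold-based cavity segmentation.

    Voxels inside ``search_region`` whose HU lies in ``hu_band`` (inclusive)
    are selected; a 1-voxel morphological closing fills pinholes; the largest
    26-connected component is kept if its volume is at least
    ``min_component_mm3``, otherwise the empty mask is returned.
    """
    low, high = hu_band
    if low >= high:
        raise ValueError(f"invalid HU band: [{low}, {high}]")
    if search_region.is_empty():
        raise ValueError("empty search region")
    sel = search_region.voxels & (volume.voxels >= low) & (volume.voxels <= high)
    if sel.any():
        sel = ndimage.binary_closing(sel, structure=_FACE_STRUCT_CLOSING, border_value=0)
        sel &= search_region.voxels
    labels, n = ndimage.label(sel, structure=_CONN26)
    if n == 0:
        return StructureMask(np.zeros(volume.shape, bool), volume, "prediction")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    component = labels == best
    if component.sum() * voxel_volume_mm3(volume) < min_component_mm3:
        component = np.zeros(volume.shape, bool)
    return StructureMask(component, volume, "prediction")


_FACE_STRUCT_CLOSING = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class BaselineSegmenter:
    """The threshold baseline bound to a fitted/supplied HU band."""

    hu_band: tuple[float, float]
    min_component_mm3: float = 100.0
    name: str = "hu_threshold_baseline"

    def __call__(self, volume: ScalarVolume, search_region: StructureMask) -> StructureMask:
        return baseline_segment(
            volume, search_region, self.hu_band, min_component_mm3=self.min_component_mm3
        )


def fit_hu_band(
    training: list[tuple[ScalarVolume, StructureMask]],
    n_sigma: float = 3.0,
    min_half_width_hu: float = 15.0,
) -> tuple[float, float]:
    """Fit the baseline's HU band from training cases (image, truth GTV).

    The band is centred on the median of per-case mean cavity HU (median so
    a minority of low-visibility cases whose cavities match brain HU do not
    drag the centre toward brain) with half-width ``max(n_sigma * median
    per-case cavity SD, min_half_width_hu)``.  Bone-level voxels are excluded
    from the statistics.
    """
    if not training:
        raise ValueError("cannot fit an HU band from an empty training set")
    means, sds = [], []
    for volume, gtv in training:
        vals = volume.voxels[gtv.voxels & (volume.voxels < BONE_HU)]
        if vals.size == 0:
            continue
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0)
    if not means:
        raise ValueError("no usable cavity voxels in the training set")
    center = float(np.median(means))
    half = max(n_sigma * float(np.median(sds)), min_half_width_hu)
    return (center - half, center + half)


def run_segmenter_over_cohort(
    segmenter: Segmenter,
    cases: list[CasePaths],
    out_dir,
    region_structure: str = "posterior_fossa",
) -> tuple[dict[str, Path], list[str]]:
    """Run a segmenter over a cohort; one predicted mask file per case.

    Cases whose files fail to load are logged and skipped.  Returns
    (case_id -> prediction path, list of failed case ids).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    predictions: dict[str, Path] = {}
    failures: list[str] = []
    for case in cases:
        try:
            volume = read_volume(case.image)
            region = read_mask(case.structures[region_structure], volume, region_structure)
            pred = segmenter(volume, region)
        except Exception as exc:  # noqa: BLE001 - per-case isolation is the point
            log.error("segmentation failed for %s: %s", case.case_id, exc)
            failures.append(case.case_id)
            continue
        path = out_dir / f"{case.case_id}.nii.gz"
        write_mask(pred, path)
        predictions[case.case_id] = path
    return predictions, failures
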