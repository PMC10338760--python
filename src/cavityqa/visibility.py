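"""Resection-cavity visibility quantification.

The workflow anchors a crop window on the GTV (its bounding box expanded by
10 voxels per side in-plane and 2 slices per side along z), excludes
high-attenuation voxels (HU >= 1000, bone) from every statistic, and computes

    contrast = mean(HU in GTV) - mean(HU in surrounding background)   [HU]
    CNR      = contrast / std(HU in background)                       [--]

where the background is everything in the crop window that is neither GTV nor
bone.  A case is *excluded* by the visibility filter when the chosen metric
falls inside the low-visibility band (default [-10, +10] HU for contrast,
[-0.5, +0.1] for CNR, band endpoints excluded-from-the-cohort, i.e. the band
is closed).

The 4-point visual score (1 = <25% of slices visible ... 4 = >75-100%) is a
human annotation: it is carried as data, never inferred from the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ScalarVolume, StructureMask

__all__ = [
    "VisibilityScore",
    "CropWindow",
    "VisibilityMetrics",
    "crop_window",
    "background_voxels",
    "compute_visibility_metrics",
    "apply_visibility_filter",
    "BONE_HU",
    "CONTRAST_BAND",
    "CNR_BAND",
]

BONE_HU = 1000.0
CONTRAST_BAND = (-10.0, 10.0)
CNR_BAND = (-0.5, 0.1)

#: slices-visible fraction bins for the ordinal score
SCORE_BINS = {1: "<25%", 2: "25-50%", 3: ">50-75%", 4: ">75-100%"}


@dataclass(frozen=True)
class VisibilityScore:
    """Ordinal manual visibility score; 4 = highest visibility."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4):
            raise ValueError(f"visibility score must be 1..4, got {self.value}")


@dataclass(frozen=True)
class CropWindow:
    """Inclusive index ranges of the GTV-anchored crop on the image grid."""

    imin: int
    imax: int
    jmin: int
    jmax: int
    kmin: int
    kmax: int
    px_xy: int = 10
    px_z: int = 2

    def slices(self) -> tuple[slice, slice, slice]:
        return (
            slice(self.imin, self.imax + 1),
            slice(self.jmin, self.jmax + 1),
            slice(self.kmin, self.kmax + 1),
        )

    def contains_box(self, box) -> bool:
        (i0, i1), (j0, j1), (k0, k1) = box
        return (
            self.imin <= i0 <= i1 <= self.imax
            and self.jmin <= j0 <= j1 <= self.jmax
            and self.kmin <= k0 <= k1 <= self.kmax
        )


@dataclass(frozen=True)
class VisibilityMetrics:
    """Bone-excluded ROI/background statistics and the derived metrics.

    ``cnr`` is None when the background standard deviation is zero (flagged
    undefined rather than infinite).
    """

    mean_roi: float
    mean_bkg: float
    std_bkg: float
    contrast: float
    cnr: float | None
    n_roi: int
    n_bkg: int


def crop_window(gtv: StructureMask, px_xy: int = 10, px_z: int = 2) -> CropWindow:
    """Bounding box of the GTV expanded by ``px_xy`` voxels per side in x/y
    and ``px_z`` slices per side in z, clipped to the volume extents."""
    if gtv.is_empty():
        raise ValueError("cannot build a crop window around an empty GTV")
    nx, ny, nz = gtv.shape
    idx = np.nonzero(gtv.voxels)
    lo = [int(a.min()) for a in idx]
    hi = [int(a.max()) for a in idx]
    return CropWindow(
        imin=max(lo[0] - px_xy, 0),
        imax=min(hi[0] + px_xy, nx - 1),
        jmin=max(lo[1] - px_xy, 0),
        jmax=min(hi[1] + px_xy, ny - 1),
        kmin=max(lo[2] - px_z, 0),
        kmax=min(hi[2] + px_z, nz - 1),
        px_xy=px_xy,
        px_z=px_z,
    )


def background_voxels(
    volume: ScalarVolume,
    gtv: StructureMask,
    window: CropWindow,
    bone_hu: float = BONE_HU,
) -> np.ndarray:
    """Boolean mask (full grid) of background voxels: inside the crop window,
    outside the GTV, and below the bone threshold.

    Raises ``ValueError`` if fewer than 2 voxels qualify (the background
    standard deviation would be degenerate).
    """
    sel = np.zeros(volume.shape, dtype=bool)
    sel[window.slices()] = True
    sel &= ~gtv.voxels
    sel &= volume.voxels < bone_hu
    if int(sel.sum()) < 2:
        raise ValueError("degenerate crop window: fewer than 2 background voxels")
    return sel


def compute_visibility_metrics(
    volume: ScalarVolume,
    gtv: StructureMask,
    px_xy: int = 10,
    px_z: int = 2,
    bone_hu: float = BONE_HU,
) -> VisibilityMetrics:
    """Contrast and CNR of the GTV against the surrounding cropped background.

    Bone exclusion (HU >= ``bone_hu``) applies to both the ROI and the
    background so the metric stays well-defined when the GTV touches bone.
    The background standard deviation is the sample (n-1) estimator.
    """
    window = crop_window(gtv, px_xy=px_xy, px_z=px_z)
    roi = gtv.voxels & (volume.voxels < bone_hu)
    n_roi = int(roi.sum())
    if n_roi < 1:
        raise ValueError("GTV contains no sub-bone-threshold voxels")
    bkg = background_voxels(volume, gtv, window, bone_hu=bone_hu)

    roi_vals = volume.voxels[roi]
    bkg_vals = volume.voxels[bkg]
    mean_roi = float(np.mean(roi_vals))
    mean_bkg = float(np.mean(bkg_vals))
    std_bkg = float(np.std(bkg_vals, ddof=1))
    contrast = mean_roi - mean_bkg
    cnr = contrast / std_bkg if std_bkg > 0 else None
    return VisibilityMetrics(
        mean_roi=mean_roi,
        mean_bkg=mean_bkg,
        std_bkg=std_bkg,
        contrast=contrast,
        cnr=cnr,
        n_roi=n_roi,
        n_bkg=int(bkg.sum()),
    )


def apply_visibility_filter(
    metrics: VisibilityMetrics,
    mode: str = "contrast",
    contrast_band: tuple[float, float] = CONTRAST_BAND,
    cnr_band: tuple[float, float] = CNR_BAND,
) -> bool:
    """Keep/exclude verdict: True = keep (high visibility).

    A case is excluded iff the selected metric lies inside the closed
    low-visibility band; values exactly on a band endpoint are excluded.
    """
    if mode == "contrast":
        lo, hi = contrast_band
        value = metrics.contrast
    elif mode == "cnr":
        lo, hi = cnr_band
        if metrics.cnr is None:
            raise ValueError("CNR undefined (zero background standard deviation)")
        value = metrics.cnr
    else:
        raise ValueError(f"unknown visibility filter mode: {mode!r}")
    return not (lo <= value <= hi)
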