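"""Anatomically constrained GTV -> CTV margin expansion.

The clinical target volume is built by expanding the gross tumor volume
(resection cavity) by a nominal margin (default 15 mm), confined to the
brain and excluding the brainstem.  When the GTV is immediately adjacent to
the brainstem (nearest approach <= an adjacency distance, default 2 mm), the
margin is reduced toward the brainstem: the locally allowed margin is

    m(v) = reduced + (nominal - reduced) * min(1, d_bs(v) / nominal)

where ``d_bs(v)`` is the distance (mm) from voxel v to the brainstem — 5 mm
at the brainstem surface, recovering linearly to the full 15 mm at >= 15 mm
away.  Expansion is realized by thresholding a spacing-aware Euclidean
distance transform, not voxel dilation, because margins are metric and CT
grids are anisotropic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import StructureMask, voxel_volume_mm3

__all__ = ["MarginSpec", "distance_from", "is_adjacent", "expand_gtv_to_ctv"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarginSpec:
    """Expansion distances (mm) and the anatomic constraints for GTV->CTV."""

    nominal_mm: float = 15.0
    reduced_mm: float = 5.0
    adjacency_mm: float = 2.0
    confine_to: str = "brain"
    exclude: str = "brainstem"

    def __post_init__(self) -> None:
        if not (0 < self.reduced_mm <= self.nominal_mm):
            raise ValueError("need 0 < reduced margin <= nominal margin")
        if self.adjacency_mm < 0:
            raise ValueError("adjacency distance must be >= 0")


def distance_from(mask: StructureMask) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) to the nearest mask voxel center;
    0 inside the mask.  Spacing-aware (anisotropic grids supported)."""
    if mask.is_empty():
        raise ValueError("distance field undefined for an empty mask")
    return ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing)


def is_adjacent(gtv: StructureMask, brainstem: StructureMask, adjacency_mm: float) -> bool:
    """True iff the GTV's nearest approach to the brainstem is <= adjacency_mm."""
    if gtv.is_empty() or brainstem.is_empty():
        raise ValueError("adjacency undefined for empty masks")
    if not gtv.same_grid(brainstem):
        raise ValueError("masks are on different grids")
    d = distance_from(brainstem)
    return bool(d[gtv.voxels].min() <= adjacency_mm)


def expand_gtv_to_ctv(
    gtv: StructureMask,
    brain: StructureMask,
    brainstem: StructureMask | None,
    spec: MarginSpec = MarginSpec(),
) -> StructureMask:
    """Expand a GTV to its CTV under the margin spec.

    Guarantees (GTV - brainstem) ⊆ CTV ⊆ brain and CTV ∩ brainstem = ∅.  If
    the GTV itself overlaps the brainstem, the overlapping voxels are still
    excluded from the CTV and the overlap volume is logged as a warning (the
    exclusion is surfaced, never silently resolved).
    """
    if gtv.is_empty():
        raise ValueError("cannot expand an empty GTV")
    if not gtv.same_grid(brain):
        raise ValueError("GTV and brain masks are on different grids")
    outside = gtv.voxels & ~brain.voxels
    if outside.any():
        raise ValueError(f"GTV extends outside the brain by {int(outside.sum())} voxels")

    d_gtv = distance_from(gtv)

    adjacent = False
    if brainstem is not None and not brainstem.is_empty():
        if not gtv.same_grid(brainstem):
            raise ValueError("GTV and brainstem masks are on different grids")
        overlap = gtv.voxels & brainstem.voxels
        if overlap.any():
            mm3 = overlap.sum() * voxel_volume_mm3(gtv.grid)
            log.warning(
                "GTV '%s' overlaps the brainstem by %.1f mm3; overlap excluded from CTV",
                gtv.label,
                mm3,
            )
        adjacent = is_adjacent(gtv, brainstem, spec.adjacency_mm)

    if adjacent:
        d_bs = distance_from(brainstem)
        allowed = spec.reduced_mm + (spec.nominal_mm - spec.reduced_mm) * np.minimum(
            1.0, d_bs / spec.nominal_mm
        )
    else:
        allowed = spec.nominal_mm

    ctv = d_gtv <= allowed
    ctv &= brain.voxels
    if brainstem is not None:
        ctv &= ~brainstem.voxels
        ctv |= gtv.voxels & ~brainstem.voxels
    else:
        ctv |= gtv.voxels
    ctv &= brain.voxels
    return StructureMask(ctv, gtv.grid, label=f"{gtv.label or 'gtv'}_ctv")
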