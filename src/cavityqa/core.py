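"""Core volumetric data types and NIfTI I/O.

Conventions shared by every other module:

* Arrays are indexed ``(i, j, k)`` = ``(x, y, z)`` with ``z`` the slice axis.
* Voxel indices are 0-based; a voxel's physical position is its **center**,
  ``origin + index * spacing`` (mm).  All distances downstream are computed in
  millimetres using the spacing, never in voxel counts, because clinical
  margins and surface distances are stated in mm/cm.
* Masks are written as unsigned 8-bit NIfTI (0/1); any nonzero value reads as
  true.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarVolume",
    "StructureMask",
    "CasePaths",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_manifest",
    "voxel_volume_mm3",
]

# Structure names a cohort manifest may carry; GTV is mandatory for scoring.
STANDARD_STRUCTURES = ("gtv", "brain", "brainstem", "posterior_fossa")


@dataclass(frozen=True)
class ScalarVolume:
    """A 3D CT image in Hounsfield units on a regular grid.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU values; must be finite.
    spacing : tuple of float
        Voxel spacing ``(dx, dy, dz)`` in mm, each strictly positive.
    origin : tuple of float
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"volume must be 3D, got {vox.ndim}D")
        if not np.all(np.isfinite(vox)):
            raise ValueError("volume contains non-finite HU values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_physical(self, index) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers for index array (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class StructureMask:
    """A binary structure mask bound to a :class:`ScalarVolume` grid."""

    voxels: np.ndarray
    grid: ScalarVolume
    label: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels).astype(bool)
        if vox.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {vox.shape} does not match grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "voxels", vox)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def count(self) -> int:
        return int(self.voxels.sum())

    def volume_mm3(self) -> float:
        return self.count() * voxel_volume_mm3(self.grid)

    def same_grid(self, other: "StructureMask") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.grid.spacing
            and self.grid.origin == other.grid.origin
        )


@dataclass
class CasePaths:
    """File locations for one case: the image plus named structure masks."""

    case_id: str
    image: Path
    structures: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case identifier must be non-empty")
        self.image = Path(self.image)
        self.structures = {k: Path(v) for k, v in self.structures.items()}


def voxel_volume_mm3(grid: ScalarVolume) -> float:
    dx, dy, dz = grid.spacing
    return dx * dy * dz


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _load_nifti(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    # get_fdata applies the header's scl_slope/inter so stored values come
    # back as HU without further rescaling here
    data = img.get_fdata()
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive spacing in header: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def read_volume(path) -> ScalarVolume:
    """Read a 3D NIfTI image as a :class:`ScalarVolume`.

    Spacing comes from the header zooms; values are interpreted as HU after
    the header's slope/intercept scaling (nibabel applies it), with no other
    rescaling.
    """
    data, spacing, origin = _load_nifti(path)
    return ScalarVolume(voxels=data, spacing=spacing, origin=origin)


def write_volume(volume: ScalarVolume, path) -> None:
    """Write a :class:`ScalarVolume` to NIfTI; round-trips bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(
        np.asarray(volume.voxels, dtype=np.float32),
        _affine(volume.spacing, volume.origin),
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path, grid: ScalarVolume, label: str = "") -> StructureMask:
    """Read a NIfTI mask onto ``grid``; nonzero voxels become true."""
    data, _, _ = _load_nifti(path)
    if data.shape != grid.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match grid shape {grid.shape}"
        )
    return StructureMask(voxels=data != 0, grid=grid, label=label or Path(path).stem)


def write_mask(mask: StructureMask, path) -> None:
    """Write a mask as uint8 0/1 NIfTI with the grid's spacing and origin."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8),
        _affine(mask.grid.spacing, mask.grid.origin),
    )
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def write_manifest(cases: list[CasePaths], path) -> None:
    """Write a cohort manifest (JSON): case id, image path, structure paths.

    Paths are stored relative to the manifest's directory when possible so a
    cohort directory can be relocated.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.parent

    def rel(p: Path) -> str:
        try:
            return str(Path(p).relative_to(base))
        except ValueError:
            return str(p)

    seen: set[str] = set()
    entries = []
    for case in cases:
        if case.case_id in seen:
            raise ValueError(f"duplicate case id in manifest: {case.case_id}")
        seen.add(case.case_id)
        entries.append(
            {
                "case_id": case.case_id,
                "image": rel(case.image),
                "structures": {k: rel(v) for k, v in case.structures.items()},
            }
        )
    path.write_text(json.dumps({"cases": entries}, indent=2))


def read_manifest(path) -> list[CasePaths]:
    path = Path(path)
    payload = json.loads(path.read_text())
    base = path.parent
    cases = []
    for entry in payload["cases"]:
        cases.append(
            CasePaths(
                case_id=entry["case_id"],
                image=base / entry["image"],
                structures={k: base / v for k, v in entry["structures"].items()},
            )
        )
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids in manifest")
    return cases


def load_case(case: CasePaths, structures: Mapping[str, str] | None = None):
    """Load a case's image and masks. Returns (ScalarVolume, dict of masks)."""
    volume = read_volume(case.image)
    wanted = dict(case.structures)
    masks = {
        name: read_mask(p, volume, label=name) for name, p in wanted.items()
    }
    return volume, masks
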