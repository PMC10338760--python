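"""Synthetic CT head phantoms with known ground truth.

Each phantom is an ellipsoidal "brain" of Gaussian-noise HU around the brain
window level (35 HU), wrapped in a constant high-attenuation skull shell
(>= 1000 HU, so the bone-exclusion rule fires on it), containing:

* a posterior-fossa subregion (the inferior-posterior part of the brain),
* a cylinder-like brainstem anterior-inferior to the fossa,
* a resection cavity: one or more balls whose mean HU is offset from brain by
  a programmed contrast ``delta_hu`` (negative for a hypodense, fluid-filled
  cavity) and which may be placed inside or outside the fossa.

Only the statistical structure that the visibility and pre-selection analyses
assume is modelled: means, noise standard deviation, connectivity and
location.  There is no CT reconstruction texture, beam hardening or
age-dependent anatomy; cavity edges are hard unless ``edge_blur_mm`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    CasePaths,
    ScalarVolume,
    StructureMask,
    write_manifest,
    write_mask,
    write_volume,
)

__all__ = ["PhantomSpec", "PhantomCase", "generate_phantom", "generate_cohort"]

AIR_HU = -1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters fully determining one phantom (seed included).

    ``delta_hu`` is the programmed cavity contrast: cavity voxels are drawn
    from Normal(brain_mean_hu + delta_hu, sigma_hu**2).  ``in_fossa`` places
    the cavity at the posterior-fossa centroid (True) or supratentorially
    (False).  ``n_components`` > 1 splits the cavity into that many disjoint
    balls (a discontinuous resection cavity).
    """

    shape: tuple[int, int, int] = (128, 128, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    brain_mean_hu: float = 35.0
    sigma_hu: float = 5.0
    skull_hu: float = 1200.0
    delta_hu: float = -40.0
    cavity_radius_mm: float = 8.0
    skull_thickness_mm: float = 16.0
    in_fossa: bool = True
    n_components: int = 1
    edge_blur_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.skull_hu < 1000:
            raise ValueError("skull HU must be >= 1000 so bone thresholding fires")
        if self.cavity_radius_mm <= 0:
            raise ValueError("cavity radius must be positive")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass(frozen=True)
class PhantomCase:
    image: ScalarVolume
    gtv: StructureMask
    brain: StructureMask
    brainstem: StructureMask
    posterior_fossa: StructureMask
    truth: PhantomSpec

    @property
    def masks(self) -> dict[str, StructureMask]:
        return {
            "gtv": self.gtv,
            "brain": self.brain,
            "brainstem": self.brainstem,
            "posterior_fossa": self.posterior_fossa,
        }


def _physical_grids(shape, spacing):
    axes = [np.arange(n) * d for n, d in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(X, Y, Z, center, semi_axes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _ball(X, Y, Z, center, radius) -> np.ndarray:
    cx, cy, cz = center
    return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= radius**2


@lru_cache(maxsize=8)
def _static_geometry(shape, spacing, skull_thickness_mm):
    """Anatomy masks shared by all phantoms on one grid (seed-independent).

    Cached because the distance transforms dominate generation time; callers
    receive copies so the cache cannot be mutated.
    """
    X, Y, Z = _physical_grids(shape, spacing)
    extent = np.array([n * d for n, d in zip(shape, spacing)])
    center = extent / 2.0

    # Brain ellipsoid occupying ~62% of each physical dimension; the rest
    # leaves room for the full skull shell inside the volume.
    brain_semi = 0.31 * extent
    brain = _ellipsoid(X, Y, Z, center, brain_semi)

    # Skull: closed shell around the brain, grown with a spacing-aware
    # distance transform so thickness is metric not voxel-based.  The default
    # thickness exceeds the visibility crop's maximum diagonal overshoot
    # beyond the brain (sqrt(10^2+10^2+5^2) ~ 15 mm at default crop and
    # spacing), mimicking a head where everything
    # just outside the brain is high-attenuation bone rather than air.
    dist_out = ndimage.distance_transform_edt(~brain, sampling=spacing)
    skull = (dist_out > 0) & (dist_out <= skull_thickness_mm)

    # Posterior fossa: inferior-posterior part of the brain (large y =
    # posterior, small z = inferior), shrunk 2 mm off the brain surface so it
    # stays strictly inside brain tissue.
    dist_in = ndimage.distance_transform_edt(brain, sampling=spacing)
    interior = dist_in >= 2.0
    fossa = interior & (Y >= center[1] + 0.15 * brain_semi[1]) & (
        Z <= center[2] - 0.25 * brain_semi[2]
    )

    # Brainstem: vertical cylinder anterior to the fossa, lower half of brain.
    bs_center_xy = (center[0], center[1] - 0.25 * brain_semi[1])
    bs_radius = 0.12 * min(brain_semi[0], brain_semi[1])
    brainstem = (
        interior
        & (((X - bs_center_xy[0]) ** 2 + (Y - bs_center_xy[1]) ** 2) <= bs_radius**2)
        & (Z <= center[2])
    )

    # Cavity placement centroids (mm), in and out of the fossa.
    com = {}
    for in_fossa in (True, False):
        if in_fossa:
            region = fossa & ~brainstem
        else:
            region = interior & (Z >= center[2] + 0.3 * brain_semi[2]) & ~fossa & ~brainstem
        com[in_fossa] = (
            np.array(ndimage.center_of_mass(region)) * np.array(spacing)
            if region.any()
            else None
        )
    return brain, skull, fossa, brainstem, com


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom; identical spec (incl. seed) gives bit-identical output.

    Raises
    ------
    ValueError
        If the cavity does not fit inside the brain at the requested location
        (collides with skull/brainstem or leaves the volume).
    """
    shape = tuple(spec.shape)
    spacing = tuple(spec.spacing)
    X, Y, Z = _physical_grids(shape, spacing)

    brain, skull, fossa, brainstem, com_table = _static_geometry(
        shape, spacing, spec.skull_thickness_mm
    )
    com = com_table[spec.in_fossa]
    if com is None:
        raise ValueError("impossible geometry: empty placement region")

    r = spec.cavity_radius_mm
    centers = []
    if spec.n_components == 1:
        centers.append(com)
    else:
        # Disjoint balls strung along x, separated by a > 1 voxel gap.
        gap = 2.0 * max(spacing)
        pitch = 2 * r + gap
        offset0 = -(spec.n_components - 1) * pitch / 2.0
        for c in range(spec.n_components):
            centers.append(com + np.array([offset0 + c * pitch, 0.0, 0.0]))

    gtv = np.zeros(shape, dtype=bool)
    for c in centers:
        gtv |= _ball(X, Y, Z, c, r)
    if not gtv.any():
        raise ValueError("impossible geometry: cavity contains no voxels")
    if (gtv & ~brain).any() or (gtv & skull).any():
        raise ValueError("cavity collides with skull or extends outside the brain")
    gtv &= ~brainstem  # invariant: GTV and brainstem are disjoint
    if not gtv.any():
        raise ValueError("cavity entirely inside the brainstem")

    # Noise-free HU means, then iid Gaussian noise over brain tissue.
    mean_img = np.full(shape, AIR_HU, dtype=np.float64)
    mean_img[brain] = spec.brain_mean_hu
    cavity_offset = np.where(gtv, spec.delta_hu, 0.0)
    if spec.edge_blur_mm > 0:
        # partial-volume-style softening of the cavity edge only; skull and
        # air stay hard so no bone HU bleeds into brain tissue
        sigma_vox = [spec.edge_blur_mm / d for d in spacing]
        cavity_offset = ndimage.gaussian_filter(cavity_offset, sigma=sigma_vox)
    mean_img = np.where(brain, mean_img + cavity_offset, mean_img)
    mean_img[skull] = spec.skull_hu

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.sigma_hu, size=shape)
    voxels = np.where(brain, mean_img + noise, mean_img)

    image = ScalarVolume(voxels=voxels, spacing=spacing)
    return PhantomCase(
        image=image,
        gtv=StructureMask(gtv, image, "gtv"),
        brain=StructureMask(brain.copy(), image, "brain"),
        brainstem=StructureMask(brainstem.copy(), image, "brainstem"),
        posterior_fossa=StructureMask(fossa.copy(), image, "posterior_fossa"),
        truth=spec,
    )


def generate_cohort(
    regimes: Sequence[tuple[PhantomSpec, int]],
    out_dir,
    seed: int,
    prefix: str = "case",
) -> tuple[list[CasePaths], Path]:
    """Generate a cohort on disk: one NIfTI image + 4 masks per case, a JSON
    manifest and a truth-table CSV for test assertions.

    Per-case seeds are derived deterministically from the master ``seed`` so a
    master seed reproduces the whole cohort byte-for-byte.  Returns the case
    list and the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_total = sum(count for _, count in regimes)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(n_total)]

    cases: list[CasePaths] = []
    truth_rows = []
    idx = 0
    for template, count in regimes:
        for _ in range(count):
            case_id = f"{prefix}{idx:03d}"
            spec = replace(template, seed=child_seeds[idx])
            case = generate_phantom(spec)
            case_dir = out_dir / case_id
            image_path = case_dir / "image.nii.gz"
            write_volume(case.image, image_path)
            structures = {}
            for name, mask in case.masks.items():
                p = case_dir / f"{name}.nii.gz"
                write_mask(mask, p)
                structures[name] = p
            cases.append(CasePaths(case_id=case_id, image=image_path, structures=structures))
            truth_rows.append(
                {
                    "case_id": case_id,
                    "delta_hu": spec.delta_hu,
                    "sigma_hu": spec.sigma_hu,
                    "n_components": spec.n_components,
                    "in_fossa": spec.in_fossa,
                    "seed": spec.seed,
                }
            )
            idx += 1

    manifest_path = out_dir / "manifest.json"
    write_manifest(cases, manifest_path)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    return cases, manifest_path
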