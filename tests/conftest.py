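"""Shared fixtures and independent brute-force oracles.

The oracles here (flood fill, all-pairs surface distances, lattice-ball
enumeration) deliberately avoid scipy.ndimage so they stay independent of
the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cavityqa.core import ScalarVolume, StructureMask
from cavityqa.phantom import PhantomSpec, generate_phantom


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> ScalarVolume:
    return ScalarVolume(voxels=np.asarray(values, dtype=float), spacing=spacing, origin=origin)


def make_mask(bool_array, volume: ScalarVolume, label: str = "m") -> StructureMask:
    return StructureMask(voxels=np.asarray(bool_array, dtype=bool), grid=volume, label=label)


def uniform_volume(shape, hu=0.0, spacing=(1.0, 1.0, 1.0)) -> ScalarVolume:
    return make_volume(np.full(shape, float(hu)), spacing=spacing)


def random_mask(rng, shape, p=0.2) -> np.ndarray:
    m = rng.random(shape) < p
    if not m.any():  # ensure non-empty
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


# ---------------------------------------------------------------- oracles

_NEIGHBORS_26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]
_NEIGHBORS_6 = [d for d in _NEIGHBORS_26 if sum(abs(x) for x in d) == 1]


def flood_fill_components(mask: np.ndarray) -> int:
    """Number of 26-connected components by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    n = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        n += 1
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            for d in _NEIGHBORS_26:
                w = tuple(a + b for a, b in zip(v, d))
                if all(0 <= wi < si for wi, si in zip(w, mask.shape)) and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
    return n


def oracle_surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Surface voxels: in the mask with >= 1 face neighbour outside the mask
    (out-of-volume counts as outside).  Explicit neighbour loop."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for v in zip(*np.nonzero(mask)):
        for d in _NEIGHBORS_6:
            w = tuple(a + b for a, b in zip(v, d))
            if not all(0 <= wi < si for wi, si in zip(w, mask.shape)) or not mask[w]:
                out[v] = True
                break
    return out


def oracle_surface_distances(a: np.ndarray, b: np.ndarray, spacing) -> tuple[float, float]:
    """All-pairs O(n^2) HD and MSD between the surface voxel sets of a and b."""
    sa = np.argwhere(oracle_surface_voxels(a)) * np.asarray(spacing)
    sb = np.argwhere(oracle_surface_voxels(b)) * np.asarray(spacing)
    d2 = ((sa[:, None, :] - sb[None, :, :]) ** 2).sum(axis=2)
    d_ab = np.sqrt(d2.min(axis=1))
    d_ba = np.sqrt(d2.min(axis=0))
    hd = max(d_ab.max(), d_ba.max())
    msd = (d_ab.mean() + d_ba.mean()) / 2.0
    return float(hd), float(msd)


def oracle_distance_field(mask: np.ndarray, spacing) -> np.ndarray:
    """All-pairs minimum distance (mm) from every voxel to the mask."""
    mask = np.asarray(mask, dtype=bool)
    targets = np.argwhere(mask) * np.asarray(spacing)
    out = np.zeros(mask.shape)
    for v in itertools.product(*(range(s) for s in mask.shape)):
        p = np.asarray(v) * np.asarray(spacing)
        out[v] = np.sqrt(((targets - p) ** 2).sum(axis=1).min())
    return out


def lattice_ball_indices(center_idx, radius_mm, spacing, shape) -> set[tuple[int, int, int]]:
    """Lattice points whose center lies within radius_mm of the center voxel."""
    sp = np.asarray(spacing, dtype=float)
    reach = [int(np.ceil(radius_mm / s)) + 1 for s in sp]
    pts = set()
    for d in itertools.product(*(range(-r, r + 1) for r in reach)):
        if np.linalg.norm(np.asarray(d) * sp) <= radius_mm:
            w = tuple(c + di for c, di in zip(center_idx, d))
            if all(0 <= wi < si for wi, si in zip(w, shape)):
                pts.add(w)
    return pts


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def default_phantom():
    """One default-geometry phantom (hypodense cavity, moderate noise)."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Reduced-grid spec for speed-sensitive multi-phantom tests; physical
    structure (spacing, HU regimes, cavity size) matches the default."""
    return PhantomSpec(shape=(96, 96, 48), seed=0)
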