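"""Distance fields, adjacency and the anatomically constrained expansion."""

import numpy as np
import pytest

from cavityqa.ctv import MarginSpec, distance_from, expand_gtv_to_ctv, is_adjacent

from conftest import (
    lattice_ball_indices,
    make_mask,
    oracle_distance_field,
    random_mask,
    uniform_volume,
)


def single_voxel_mask(shape, idx, vol):
    arr = np.zeros(shape, bool)
    arr[idx] = True
    return make_mask(arr, vol)


class TestMarginSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            MarginSpec(nominal_mm=10, reduced_mm=15)
        with pytest.raises(ValueError):
            MarginSpec(reduced_mm=0)
        with pytest.raises(ValueError):
            MarginSpec(adjacency_mm=-1)


class TestDistanceFrom:
    def test_spacing_aware_neighbor_distance(self):
        vol = uniform_volume((4, 4, 4), spacing=(1.0, 1.0, 2.5))
        d = distance_from(single_voxel_mask((4, 4, 4), (1, 1, 1), vol))
        assert d[1, 1, 2] == pytest.approx(2.5)  # one step along z
        assert d[2, 1, 1] == pytest.approx(1.0)  # one step along x
        assert d[1, 1, 1] == 0.0

    def test_zero_inside_mask(self):
        vol = uniform_volume((6, 6, 6))
        arr = np.zeros((6, 6, 6), bool)
        arr[1:4, 1:4, 1:4] = True
        d = distance_from(make_mask(arr, vol))
        assert (d[arr] == 0).all()

    def test_empty_mask_rejected(self):
        vol = uniform_volume((4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            distance_from(make_mask(np.zeros((4, 4, 4), bool), vol))

    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (0.97, 0.97, 2.5)])
    def test_matches_all_pairs_oracle(self, spacing):
        rng = np.random.default_rng(5)
        for _ in range(5):
            arr = random_mask(rng, (7, 7, 7), p=0.1)
            vol = uniform_volume((7, 7, 7), spacing=spacing)
            d = distance_from(make_mask(arr, vol))
            np.testing.assert_allclose(d, oracle_distance_field(arr, spacing), atol=1e-9)


class TestAdjacency:
    def test_touching(self):
        vol = uniform_volume((8, 8, 8))
        gtv = single_voxel_mask((8, 8, 8), (3, 3, 3), vol)
        bs = single_voxel_mask((8, 8, 8), (4, 3, 3), vol)
        assert is_adjacent(gtv, bs, 2.0)

    def test_far_apart(self):
        vol = uniform_volume((40, 8, 8))
        gtv = single_voxel_mask((40, 8, 8), (2, 3, 3), vol)
        bs = single_voxel_mask((40, 8, 8), (35, 3, 3), vol)  # 33 mm away
        assert not is_adjacent(gtv, bs, 2.0)

    def test_exactly_at_threshold_counts_as_adjacent(self):
        """Nearest approach exactly 2.0 mm satisfies the <= rule."""
        vol = uniform_volume((8, 8, 8), spacing=(1.0, 1.0, 2.0))
        gtv = single_voxel_mask((8, 8, 8), (3, 3, 3), vol)
        bs = single_voxel_mask((8, 8, 8), (3, 3, 4), vol)  # one z step = 2.0 mm
        assert is_adjacent(gtv, bs, 2.0)

    def test_empty_masks_rejected(self):
        vol = uniform_volume((4, 4, 4))
        gtv = single_voxel_mask((4, 4, 4), (1, 1, 1), vol)
        empty = make_mask(np.zeros((4, 4, 4), bool), vol)
        with pytest.raises(ValueError):
            is_adjacent(gtv, empty, 2.0)


def all_brain(shape, spacing=(1.0, 1.0, 1.0)):
    vol = uniform_volume(shape, spacing=spacing)
    return vol, make_mask(np.ones(shape, bool), vol, "brain")


class TestExpansion:
    def test_single_voxel_expands_to_brute_force_lattice_ball(self):
        """15 mm expansion of a point GTV equals the enumerated lattice ball."""
        shape = (40, 40, 40)
        vol, brain = all_brain(shape)
        gtv = single_voxel_mask(shape, (20, 20, 20), vol)
        ctv = expand_gtv_to_ctv(gtv, brain, None, MarginSpec())
        got = set(map(tuple, np.argwhere(ctv.voxels)))
        expected = lattice_ball_indices((20, 20, 20), 15.0, (1.0, 1.0, 1.0), shape)
        assert got == expected

    def test_anisotropic_point_expansion_matches_enumeration(self):
        shape = (40, 40, 16)
        vol, brain = all_brain(shape, spacing=(1.0, 1.0, 2.5))
        gtv = single_voxel_mask(shape, (20, 20, 8), vol)
        ctv = expand_gtv_to_ctv(gtv, brain, None, MarginSpec())
        got = set(map(tuple, np.argwhere(ctv.voxels)))
        expected = lattice_ball_indices((20, 20, 8), 15.0, (1.0, 1.0, 2.5), shape)
        assert got == expected

    def test_confined_to_brain(self):
        shape = (30, 30, 30)
        vol = uniform_volume(shape)
        brain_arr = np.zeros(shape, bool)
        brain_arr[5:25, 5:25, 5:25] = True
        brain = make_mask(brain_arr, vol, "brain")
        gtv = single_voxel_mask(shape, (6, 15, 15), vol)  # abuts brain boundary
        ctv = expand_gtv_to_ctv(gtv, brain, None, MarginSpec())
        assert not (ctv.voxels & ~brain_arr).any()
        assert ctv.voxels[6, 15, 15]

    def test_gtv_outside_brain_rejected(self):
        shape = (20, 20, 20)
        vol = uniform_volume(shape)
        brain_arr = np.zeros(shape, bool)
        brain_arr[5:15, 5:15, 5:15] = True
        gtv = single_voxel_mask(shape, (1, 1, 1), vol)
        with pytest.raises(ValueError, match="outside"):
            expand_gtv_to_ctv(gtv, make_mask(brain_arr, vol), None, MarginSpec())

    def test_empty_gtv_rejected(self):
        shape = (10, 10, 10)
        vol, brain = all_brain(shape)
        with pytest.raises(ValueError, match="empty"):
            expand_gtv_to_ctv(make_mask(np.zeros(shape, bool), vol), brain, None, MarginSpec())

    def test_directional_reduction_toward_brainstem(self):
        """Margin is ~5 mm at the brainstem surface and recovers to 15 mm at
        >= 15 mm from it."""
        shape = (70, 70, 40)
        vol, brain = all_brain(shape)
        bs_arr = np.zeros(shape, bool)
        bs_arr[0:10, :, :] = True  # slab brainstem
        brainstem = make_mask(bs_arr, vol, "brainstem")
        gtv_arr = np.zeros(shape, bool)
        gtv_arr[11:14, 30:40, 15:25] = True  # 1 mm from the slab: adjacent
        gtv = make_mask(gtv_arr, vol, "gtv")
        spec = MarginSpec()
        assert is_adjacent(gtv, brainstem, spec.adjacency_mm)
        ctv = expand_gtv_to_ctv(gtv, brain, brainstem, spec)
        d_gtv = distance_from(gtv)
        d_bs = distance_from(brainstem)
        m_allowed = spec.reduced_mm + (spec.nominal_mm - spec.reduced_mm) * np.minimum(
            1.0, d_bs / spec.nominal_mm
        )
        # CTV == the stated construction
        expected = (d_gtv <= m_allowed) & brain.voxels & ~bs_arr | (gtv_arr & ~bs_arr)
        np.testing.assert_array_equal(ctv.voxels, expected)
        # near the brainstem (within 1 mm of its surface) reach stays <= ~5.7 mm
        near = ctv.voxels & (d_bs > 0) & (d_bs <= 1.0)
        assert near.any()
        assert d_gtv[near].max() <= spec.reduced_mm + (spec.nominal_mm - spec.reduced_mm) / spec.nominal_mm + 1e-9
        # far from the brainstem (>= 15 mm) the full 15 mm reach is restored
        far_candidates = (d_bs >= spec.nominal_mm) & (d_gtv <= spec.nominal_mm) & brain.voxels
        assert far_candidates.any()
        assert ctv.voxels[far_candidates].all()

    def test_invariants_on_randomized_geometries(self):
        rng = np.random.default_rng(21)
        shape = (24, 24, 16)
        spec = MarginSpec(nominal_mm=6.0, reduced_mm=2.0, adjacency_mm=2.0)
        for _ in range(25):
            vol = uniform_volume(shape, spacing=(1.0, 1.0, 1.5))
            brain_arr = np.zeros(shape, bool)
            brain_arr[2:22, 2:22, 2:14] = True
            bs_arr = np.zeros(shape, bool)
            bi = rng.integers(2, 18)
            bs_arr[bi : bi + 3, 2:22, 2:14] = True
            gi = rng.integers(2, 20, size=3)
            gtv_arr = np.zeros(shape, bool)
            gtv_arr[gi[0] : gi[0] + 2, gi[1] : gi[1] + 2, min(gi[2], 12) : min(gi[2], 12) + 2] = True
            gtv_arr &= brain_arr
            gtv_arr &= ~bs_arr
            if not gtv_arr.any():
                continue
            brain = make_mask(brain_arr, vol, "brain")
            bs = make_mask(bs_arr, vol, "brainstem")
            gtv = make_mask(gtv_arr, vol, "gtv")
            ctv = expand_gtv_to_ctv(gtv, brain, bs, spec)
            assert (gtv_arr & ~bs_arr & ~ctv.voxels).sum() == 0  # GTV-bs subset CTV
            assert not (ctv.voxels & ~brain_arr).any()  # confined to brain
            assert not (ctv.voxels & bs_arr).any()  # brainstem excluded

    def test_monotone_in_margin_and_brainstem(self):
        shape = (30, 30, 20)
        vol, brain = all_brain(shape)
        gtv = single_voxel_mask(shape, (15, 15, 10), vol)
        bs_small = np.zeros(shape, bool)
        bs_small[0:2, :, :] = True
        bs_big = bs_small.copy()
        bs_big[0:6, :, :] = True
        small = make_mask(bs_small, vol)
        big = make_mask(bs_big, vol)
        c_small = expand_gtv_to_ctv(gtv, brain, small, MarginSpec(nominal_mm=10))
        c_big_margin = expand_gtv_to_ctv(gtv, brain, small, MarginSpec(nominal_mm=14))
        assert (c_small.voxels & ~c_big_margin.voxels).sum() == 0  # larger margin never shrinks
        c_big_bs = expand_gtv_to_ctv(gtv, brain, big, MarginSpec(nominal_mm=10))
        assert (c_big_bs.voxels & ~c_small.voxels).sum() == 0  # larger brainstem never grows

    def test_isotropic_ball_gtv_stays_near_analytic_ball(self):
        """Expansion of a ball GTV approximates the analytic r+margin ball to
        within one voxel diagonal (Hausdorff sense)."""
        shape = (40, 40, 40)
        vol, brain = all_brain(shape)
        idx = np.indices(shape)
        c = np.array([20, 20, 20])
        r_gtv = 4.0
        gtv_arr = ((idx - c[:, None, None, None]) ** 2).sum(axis=0) <= r_gtv**2
        gtv = make_mask(gtv_arr, vol, "gtv")
        margin = 8.0
        ctv = expand_gtv_to_ctv(gtv, brain, None, MarginSpec(nominal_mm=margin))
        dist_c = np.sqrt(((idx - c[:, None, None, None]) ** 2).sum(axis=0))
        diag = np.sqrt(3.0)
        inner = dist_c <= r_gtv + margin - diag
        outer = dist_c <= r_gtv + margin + diag
        assert (inner & ~ctv.voxels).sum() == 0
        assert (ctv.voxels & ~outer).sum() == 0

    def test_gtv_overlapping_brainstem_warns_and_excludes(self, caplog):
        import logging

        shape = (20, 20, 20)
        vol, brain = all_brain(shape)
        gtv_arr = np.zeros(shape, bool)
        gtv_arr[8:12, 8:12, 8:12] = True
        bs_arr = np.zeros(shape, bool)
        bs_arr[10:14, 8:12, 8:12] = True
        gtv = make_mask(gtv_arr, vol, "gtv")
        bs = make_mask(bs_arr, vol, "brainstem")
        with caplog.at_level(logging.WARNING, logger="cavityqa.ctv"):
            ctv = expand_gtv_to_ctv(gtv, brain, bs, MarginSpec())
        assert "overlap" in caplog.text.lower()
        assert not (ctv.voxels & bs_arr).any()
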