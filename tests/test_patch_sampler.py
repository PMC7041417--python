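"""Seed grids, brain-fraction filtering, boundary sampling and tiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gliounet as g
from gliounet.patch_sampler import (
    NoTumorWarning,
    PatchSpec,
    padded_shape,
    training_patch_inventory,
    save_patchset,
    load_patchset,
)
from tests.conftest import random_label_volume


def brute_force_boundary(wt: np.ndarray) -> set:
    """Independent 6-neighbour scan: voxels differing from any face neighbour.

    Only in-bounds neighbours are compared, matching the edge handling of
    the library interface the pipeline exposes.
    """
    out = set()
    shape = wt.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = wt[x, y, z]
                for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                        if wt[nx, ny, nz] != v:
                            out.add((x, y, z))
                            break
    return out


class TestSeedGrid:
    @pytest.mark.parametrize(
        "shape,size,stride,expected",
        [
            ((64, 64, 64), 64, 64, 1),
            ((240, 240, 155), 64, 64, 4 * 4 * 3),  # padded to 256x256x192
            ((128, 128, 128), 64, 32, 27),  # (128-64)/32+1 = 3 per axis
        ],
    )
    def test_lattice_counts(self, shape, size, stride, expected):
        assert len(g.seed_grid(shape, size, stride)) == expected

    def test_nonoverlapping_tiles_cover_padded_grid_once(self):
        specs = g.seed_grid((240, 240, 155), 64)
        cover = np.zeros(padded_shape((240, 240, 155), 64), np.int8)
        for s in specs:
            cover[s.slices] += 1
        assert (cover == 1).all()


class TestBrainFractionFilter:
    def test_strictly_greater_than_threshold(self):
        # mask exactly 60% of a 10^3 patch: must be rejected ("more than 60%")
        mask = np.zeros((10, 10, 10), bool)
        mask[:6] = True
        specs = [PatchSpec((0, 0, 0), 10)]
        bm = g.BrainMask(mask)
        assert g.brain_fraction_filter(specs, bm, 0.6) == []
        assert g.brain_fraction_filter(specs, bm, 0.59) == specs

    def test_half_filled_patch_threshold_cases(self):
        mask = np.zeros((64, 64, 64), bool)
        mask[:32] = True  # fraction exactly 0.5
        specs = [PatchSpec((0, 0, 0), 64)]
        bm = g.BrainMask(mask)
        assert g.brain_fraction_filter(specs, bm, 0.6) == []
        assert g.brain_fraction_filter(specs, bm, 0.4) == specs

    @given(st.integers(0, 8), st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, seed, pct):
        rng = np.random.default_rng(seed)
        mask = g.BrainMask(rng.random((24, 24, 24)) < 0.5)
        specs = g.seed_grid((24, 24, 24), 8, 8)
        lo = pct / 101.0
        hi = min(lo + 0.2, 0.999)
        kept_hi = set(map(id, g.brain_fraction_filter(specs, mask, hi)))
        kept_lo = set(map(id, g.brain_fraction_filter(specs, mask, lo)))
        assert kept_hi <= kept_lo


class TestBoundaryVoxels:
    def test_single_voxel_boundary_is_voxel_plus_face_neighbours(self):
        labels = np.zeros((9, 9, 9), np.int16)
        labels[4, 4, 4] = 2
        b = g.wt_boundary_voxels(g.LabelVolume(labels))
        assert len(b) == 7
        got = {tuple(v) for v in b}
        expected = {(4, 4, 4), (3, 4, 4), (5, 4, 4), (4, 3, 4),
                    (4, 5, 4), (4, 4, 3), (4, 4, 5)}
        assert got == expected

    def test_solid_cube_shell_plus_exterior_faces(self):
        labels = np.zeros((9, 9, 9), np.int16)
        labels[3:6, 3:6, 3:6] = 4
        b = g.wt_boundary_voxels(g.LabelVolume(labels))
        got = {tuple(v) for v in b}
        # 26 shell voxels (all but the centre) + 6*9 exterior face voxels
        assert (4, 4, 4) not in got
        assert len(got) == 26 + 54

    def test_no_tumor_warns_and_returns_empty(self):
        labels = g.LabelVolume(np.zeros((5, 5, 5), np.int16))
        with pytest.warns(NoTumorWarning):
            b = g.wt_boundary_voxels(labels)
        assert len(b) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_scan(self, seed, rng):
        labels = random_label_volume(np.random.default_rng(seed), (16, 16, 16))
        got = {tuple(v) for v in g.wt_boundary_voxels(labels)}
        wt = np.isin(labels.data, (1, 2, 4))
        assert got == brute_force_boundary(wt)


class TestBoundarySampling:
    def test_thirty_percent_of_100_is_30(self, rng):
        boundary = rng.choice(64 ** 3, size=100, replace=False)
        coords = np.stack(np.unravel_index(boundary, (64, 64, 64)), axis=1)
        specs = g.sample_boundary_patches(coords, (64, 64, 64), 0.3, 16, 0)
        assert len(specs) == 30

    def test_deterministic_given_seed(self, rng):
        coords = rng.integers(0, 100, size=(200, 3))
        a = g.sample_boundary_patches(coords, (100, 100, 100), 0.3, 32, 5)
        b = g.sample_boundary_patches(coords, (100, 100, 100), 0.3, 32, 5)
        assert a == b

    def test_corner_clipped_into_padded_grid(self):
        coords = np.array([[2, 2, 2]])
        specs = g.sample_boundary_patches(coords, (240, 240, 240), 1.0, 64, 0)
        assert specs[0].corner == (0, 0, 0)
        # centre near the high edge clips to padded-shape - size
        coords = np.array([[239, 239, 239]])
        specs = g.sample_boundary_patches(coords, (240, 240, 240), 1.0, 64, 0)
        assert specs[0].corner == (192, 192, 192)

    def test_empty_boundary_gives_empty_list(self):
        assert g.sample_boundary_patches(np.empty((0, 3)), (64,) * 3, 0.3, 16, 0) == []


class TestExtractAssemble:
    def test_patch_equals_subblock(self, phantom48):
        vol, labels = phantom48
        spec = PatchSpec((8, 4, 12), 16)
        ps = g.extract_patches(vol, labels, [spec])
        np.testing.assert_array_equal(
            ps.images[0], vol.data[:, 8:24, 4:20, 12:28])
        np.testing.assert_array_equal(ps.labels[0], labels.data[8:24, 4:20, 12:28])

    def test_padding_margin_is_exact_zero(self, phantom48):
        vol, _ = phantom48  # 48^3, pad to 64^3 with size 32 -> margin beyond 48
        spec = PatchSpec((32, 32, 32), 32)
        ps = g.extract_patches(vol, None, [spec])
        assert np.all(ps.images[0][:, 16:, :, :] == 0.0)

    def test_out_of_bounds_spec_rejected(self, phantom48):
        vol, _ = phantom48
        with pytest.raises(ValueError, match="exceeds"):
            g.extract_patches(vol, None, [PatchSpec((60, 0, 0), 32)])

    def test_tile_voxel_count_matches_padded_grid(self):
        shape = (240, 240, 155)
        specs = g.seed_grid(shape, 64)
        total = sum(s.size ** 3 for s in specs)
        assert total == 256 * 256 * 192

    def test_roundtrip_identity_on_phantom_labels(self, phantom48):
        vol, labels = phantom48
        specs = g.seed_grid(vol.shape, 16)
        ps = g.extract_patches(vol, labels, specs)
        out = g.assemble_prediction(list(zip(ps.specs, ps.labels)), vol.shape)
        np.testing.assert_array_equal(out, labels.data)

    def test_missing_tile_rejected(self, phantom48):
        vol, labels = phantom48
        specs = g.seed_grid(vol.shape, 16)
        ps = g.extract_patches(vol, labels, specs)
        tiles = list(zip(ps.specs, ps.labels))[:-1]
        with pytest.raises(ValueError, match="missing"):
            g.assemble_prediction(tiles, vol.shape)

    def test_overlapping_tiles_rejected(self, phantom48):
        vol, labels = phantom48
        specs = g.seed_grid(vol.shape, 16)
        ps = g.extract_patches(vol, labels, specs)
        tiles = list(zip(ps.specs, ps.labels))
        tiles[1] = (tiles[0][0], tiles[1][1])
        with pytest.raises(ValueError, match="overlap|missing"):
            g.assemble_prediction(tiles, vol.shape)

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=10, deadline=None)
    def test_roundtrip_identity_random_volumes(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(int(s) for s in rng.integers(10, 40, 3))
        labels = rng.integers(0, 5, shape).astype(np.int16)
        labels[labels == 3] = 0
        vol = g.MultiChannelVolume(rng.random((4,) + shape, dtype=np.float32))
        lv = g.LabelVolume(labels)
        specs = g.seed_grid(shape, 16)
        ps = g.extract_patches(vol, lv, specs)
        out = g.assemble_prediction(list(zip(ps.specs, ps.labels)), shape)
        np.testing.assert_array_equal(out, labels)


class TestInventoryAndPersistence:
    def test_inventory_contains_both_origins(self, phantom48):
        vol, labels = phantom48
        mask = g.derive_brain_mask(vol)
        ps = training_patch_inventory(vol, labels, mask, patch_size=16,
                                      rng_seed=3, max_boundary_patches=20)
        origins = {s.origin for s in ps.specs}
        assert origins == {"grid-seed", "boundary-weighted"}
        assert ps.rng_seed == 3

    def test_patchset_roundtrip(self, tmp_path, phantom48):
        vol, labels = phantom48
        mask = g.derive_brain_mask(vol)
        ps = training_patch_inventory(vol, labels, mask, patch_size=16,
                                      rng_seed=3, max_boundary_patches=10)
        save_patchset(ps, tmp_path / "patches")
        back = load_patchset(tmp_path / "patches")
        assert back.specs == ps.specs
        np.testing.assert_array_equal(back.images, ps.images)
        np.testing.assert_array_equal(back.labels, ps.labels)
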