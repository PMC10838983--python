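import math

import numpy as np
import pytest

from perishell.layers import (
    LesionSpec,
    build_layers,
    flip_contralateral,
    lesion_distance_mm,
    normalized_lesion_volume,
)
from perishell.volumes import LabeledVolume

from _oracles import brute_force_layer_labels
from conftest import make_volume, symmetric_affine


class TestNormalizedVolume:
    def _spec(self, n_voxels, icv, voxel=1.0):
        side = int(round(n_voxels ** (1 / 3)))
        data = np.zeros((side + 4, side + 4, side + 4), dtype=np.uint8)
        data[2:2 + side, 2:2 + side, 2:2 + side] = 1
        return LesionSpec(make_volume(data, voxel=voxel), icv_mm3=icv)

    def test_formula_example(self):
        # 3000 mm^3 lesion, 1.5e6 mm^3 ICV
        spec = LesionSpec(
            make_volume(np.pad(np.ones((10, 10, 30), np.uint8), 1)), icv_mm3=1.5e6
        )
        v, logv = normalized_lesion_volume(spec)
        assert v == pytest.approx(2000.0)
        assert logv == pytest.approx(math.log10(2000.0), abs=1e-6)
        assert logv == pytest.approx(3.3010, abs=1e-4)

    def test_unit_lesion(self):
        data = np.zeros((5, 5, 5), np.uint8)
        data[2, 2, 2] = 1
        v, logv = normalized_lesion_volume(LesionSpec(make_volume(data), icv_mm3=1e6))
        assert v == pytest.approx(1.0)
        assert logv == pytest.approx(0.0, abs=1e-12)

    def test_empty_lesion_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            LesionSpec(make_volume(np.zeros((4, 4, 4), np.uint8)), icv_mm3=1e6)

    def test_nonpositive_icv_rejected(self):
        data = np.zeros((4, 4, 4), np.uint8)
        data[1, 1, 1] = 1
        with pytest.raises(ValueError, match="intracranial"):
            LesionSpec(make_volume(data), icv_mm3=0.0)


class TestFlip:
    def test_involution(self, rng):
        mask = make_volume((rng.random((8, 6, 6)) > 0.6).astype(np.uint8))
        twice = flip_contralateral(flip_contralateral(mask))
        assert np.array_equal(twice.data, mask.data)

    def test_single_voxel_world_coordinates(self):
        # voxel at world x=+12 must land at world x=-12
        data = np.zeros((25, 5, 5), np.uint8)
        aff = symmetric_affine((25, 5, 5), voxel=1.0)  # world x = i - 12
        data[24, 2, 2] = 1  # x = +12
        flipped = flip_contralateral(LabeledVolume(data, aff))
        assert flipped.data.sum() == 1
        assert tuple(np.argwhere(flipped.data)[0]) == (0, 2, 2)  # x = -12

    def test_symmetric_mask_unchanged(self):
        data = np.zeros((8, 8, 8), np.uint8)
        data[3:5, 2:6, 2:6] = 1  # symmetric about the midplane between 3 and 4
        vol = make_volume(data)
        assert np.array_equal(flip_contralateral(vol).data, data)

    def test_count_preserved(self, rng):
        mask = make_volume((rng.random((10, 7, 7)) > 0.5).astype(np.uint8))
        assert flip_contralateral(mask).data.sum() == mask.data.sum()

    def test_asymmetric_grid_rejected(self):
        data = np.zeros((6, 4, 4), np.uint8)
        data[1, 1, 1] = 1
        aff = np.eye(4)  # x spans 0..5, not symmetric about 0
        with pytest.raises(ValueError, match="symmetric"):
            flip_contralateral(LabeledVolume(data, aff))


def _cubic_fixture(voxel=1.0, nx=64, ny=36, nz=36, cube=5, center_x_mm=14.0):
    """All-GM box with a cubic lesion in the +x hemisphere."""
    shape = (nx, ny, nz)
    aff = symmetric_affine(shape, voxel)
    gm = np.ones(shape, dtype=np.uint8)
    xs = (np.arange(nx) - (nx - 1) / 2.0) * voxel
    hemis = np.where(xs < 0, 1, 2).astype(np.uint8)[:, None, None] * gm
    lesion = np.zeros(shape, dtype=np.uint8)
    ci = int(np.argmin(np.abs(xs - center_x_mm)))
    h = cube // 2
    cy, cz = ny // 2, nz // 2
    lesion[ci - h:ci + h + 1, cy - h:cy + h + 1, cz - h:cz + h + 1] = 1
    return (
        LabeledVolume(lesion, aff),
        LabeledVolume(gm, aff),
        LabeledVolume(hemis, aff),
    )


class TestBuildLayers:
    def test_cubic_lesion_matches_exhaustive_oracle(self):
        lesion, gm, hemis = _cubic_fixture(nx=56, ny=32, nz=32)
        layers = build_layers(lesion, gm, hemis)
        hemi_ok = hemis.data == 2
        labels = brute_force_layer_labels(
            lesion.as_bool(), gm.as_bool(), hemi_ok, lesion.voxel_size
        )
        for k in range(1, 11):
            assert np.array_equal(layers.ipsi_layers[k - 1], labels == k), f"layer {k}"

    def test_band_union_is_all_gm_within_20mm(self):
        lesion, gm, hemis = _cubic_fixture(nx=56, ny=32, nz=32)
        layers = build_layers(lesion, gm, hemis)
        d = lesion_distance_mm(lesion)
        expected = (d > 0) & (d <= 20.0) & gm.as_bool() & (hemis.data == 2)
        assert np.array_equal(layers.union("ipsi"), expected)
        assert layers.band_mm() == pytest.approx(20.0)

    def test_gm_equal_to_lesion_gives_empty_layers(self):
        lesion, _, hemis = _cubic_fixture(nx=40, ny=24, nz=24)
        layers = build_layers(lesion, lesion, hemis)
        assert all(m.sum() == 0 for m in layers.ipsi_layers)
        assert all(m.sum() == 0 for m in layers.contra_layers)

    def test_layerset_invariants(self, small_anatomy):
        layers = build_layers(small_anatomy.lesion, small_anatomy.gm, small_anatomy.hemis)
        gm = small_anatomy.gm.as_bool()
        les = small_anatomy.lesion.as_bool()
        contra_les = layers.contra_lesion.as_bool()
        right = small_anatomy.hemis.data == 2
        left = small_anatomy.hemis.data == 1
        seen = np.zeros(gm.shape, dtype=bool)
        for m in layers.ipsi_layers:
            assert not (m & seen).any(), "ipsi layers overlap"
            seen |= m
            assert not (m & les).any()
            assert (m <= gm).all()
            assert not (m & left).any()
        seen[:] = False
        for m in layers.contra_layers:
            assert not (m & seen).any(), "contra layers overlap"
            seen |= m
            assert not (m & contra_les).any()
            assert (m <= gm).all()
            assert not (m & right).any()

    def test_nesting_distances(self, small_anatomy):
        layers = build_layers(small_anatomy.lesion, small_anatomy.gm, small_anatomy.hemis)
        d = lesion_distance_mm(small_anatomy.lesion)
        for k, m in enumerate(layers.ipsi_layers, start=1):
            if m.any():
                assert d[m].min() > (k - 1) * 2.0
                assert d[m].max() <= k * 2.0

    def test_mirror_symmetry_on_symmetric_anatomy(self, small_anatomy):
        layers = build_layers(small_anatomy.lesion, small_anatomy.gm, small_anatomy.hemis)
        for k in range(10):
            ipsi = small_anatomy.lesion.with_data(layers.ipsi_layers[k].astype(np.uint8))
            assert np.array_equal(
                flip_contralateral(ipsi).data.astype(bool), layers.contra_layers[k]
            ), f"layer {k + 1}"

    def test_anisotropic_voxels_use_mm(self):
        # on a 2-mm grid, layer 1 (0-2 mm) is exactly the 6-connected border
        lesion, gm, hemis = _cubic_fixture(voxel=2.0, nx=40, ny=24, nz=24,
                                           cube=3, center_x_mm=16.0)
        layers = build_layers(lesion, gm, hemis)
        d = lesion_distance_mm(lesion)
        assert np.array_equal(layers.ipsi_layers[0],
                              (d > 0) & (d <= 2.0) & (hemis.data == 2))

    def test_dilation_mode_invariants(self):
        lesion, gm, hemis = _cubic_fixture(nx=48, ny=28, nz=28)
        layers = build_layers(lesion, gm, hemis, shell_mode="dilation")
        seen = np.zeros(gm.shape, dtype=bool)
        for m in layers.ipsi_layers:
            assert not (m & seen).any()
            seen |= m
            assert not (m & lesion.as_bool()).any()

    def test_crossing_lesion_rejected(self):
        lesion, gm, hemis = _cubic_fixture()
        bad = lesion.with_data(np.roll(lesion.data, -lesion.data.shape[0] // 4, axis=0))
        # rolled lesion straddles the midline
        bad.data[bad.data.shape[0] // 2 - 1: bad.data.shape[0] // 2 + 1, :, :] |= np.uint8(0)
        if (bad.as_bool() & (hemis.data == 1)).any() and (bad.as_bool() & (hemis.data == 2)).any():
            with pytest.raises(ValueError, match="midline"):
                build_layers(bad, gm, hemis)

    def test_empty_lesion_rejected(self):
        _, gm, hemis = _cubic_fixture()
        empty = gm.with_data(np.zeros_like(gm.data))
        with pytest.raises(ValueError, match="empty"):
            build_layers(empty, gm, hemis)
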