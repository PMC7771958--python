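"""Overlap and distance metrics against hand values and brute force."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from massp.grids import LabelVolume, VolumeGrid
from massp.metrics import overlap_metrics, overlap_report, volume_bias


def _lv(mask: np.ndarray, sid: int = 1, voxel: float = 1.0) -> LabelVolume:
    grid = VolumeGrid.isotropic(mask.shape[0], voxel)
    return LabelVolume(grid, np.where(mask, sid, 0), {sid: "s"})


def brute_force_asd(ma: np.ndarray, mb: np.ndarray) -> float:
    """All-pairs boundary-distance oracle."""

    def boundary(m):
        out = np.zeros_like(m)
        for v in np.argwhere(m):
            x, y, z = v
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                p = (x + dx, y + dy, z + dz)
                if any(c < 0 or c >= s for c, s in zip(p, m.shape)) or not m[p]:
                    out[x, y, z] = True
                    break
        return np.argwhere(out).astype(float)

    ba, bb = boundary(ma), boundary(mb)
    d_ab = cKDTree(bb).query(ba)[0].mean()
    d_ba = cKDTree(ba).query(bb)[0].mean()
    return 0.5 * (d_ab + d_ba)


def brute_force_dilated_dice(ma: np.ndarray, mb: np.ndarray) -> float:
    """Set-arithmetic oracle for the one-voxel-tolerance overlap."""
    def dilate(m):
        out = m.copy()
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    out |= np.roll(
                        np.pad(m, 1), (dx, dy, dz), axis=(0, 1, 2)
                    )[1:-1, 1:-1, 1:-1]
        return out

    return ((ma & dilate(mb)).sum() + (mb & dilate(ma)).sum()) / (ma.sum() + mb.sum())


def test_identity_is_perfect():
    m = np.zeros((12, 12, 12), bool)
    m[3:9, 3:9, 3:9] = True
    e = overlap_metrics(_lv(m), _lv(m), 1)
    assert e.dice == 1.0 and e.dilated_dice == 1.0 and e.asd_voxels == 0.0


def test_disjoint_sets_zero_overlap():
    a = np.zeros((16, 16, 16), bool)
    b = np.zeros_like(a)
    a[2:5, 2:5, 2:5] = True
    b[10:13, 10:13, 10:13] = True
    e = overlap_metrics(_lv(a), _lv(b), 1)
    assert e.dice == 0.0 and e.dilated_dice == 0.0


def test_one_voxel_shift_hand_values():
    a = np.zeros((14, 14, 14), bool)
    a[2:12, 2:12, 2:12] = True  # 10^3 cube
    b = np.roll(a, 1, axis=0)
    e = overlap_metrics(_lv(a), _lv(b), 1)
    assert e.dice == pytest.approx(2 * 10 * 10 * 9 / 2000.0)  # 0.9
    assert e.dilated_dice == 1.0
    assert e.asd_voxels == pytest.approx(brute_force_asd(a, b))


def test_asd_and_dilated_match_brute_force_on_random_masks(rng):
    from scipy import ndimage

    for _ in range(5):
        a = ndimage.binary_closing(rng.random((12, 12, 12)) < 0.35)
        b = ndimage.binary_closing(rng.random((12, 12, 12)) < 0.35)
        if not (a.any() and b.any()):
            continue
        e = overlap_metrics(_lv(a), _lv(b), 1)
        assert e.asd_voxels == pytest.approx(brute_force_asd(a, b), abs=1e-12)
        assert e.dilated_dice == pytest.approx(brute_force_dilated_dice(a, b))
        assert e.dilated_dice >= e.dice


def test_dice_translation_invariance(rng):
    a = rng.random((12, 12, 12)) < 0.3
    b = rng.random((12, 12, 12)) < 0.3
    e1 = overlap_metrics(_lv(a), _lv(b), 1)
    shift = (2, 1, 0)
    e2 = overlap_metrics(
        _lv(np.roll(a, shift, (0, 1, 2))), _lv(np.roll(b, shift, (0, 1, 2))), 1
    )
    assert e1.dice == pytest.approx(e2.dice)


def test_asd_in_mm_scales_with_voxel_size():
    a = np.zeros((14, 14, 14), bool)
    a[2:12, 2:12, 2:12] = True
    b = np.roll(a, 1, axis=0)
    e = overlap_metrics(_lv(a, voxel=0.7), _lv(b, voxel=0.7), 1)
    assert e.asd_mm == pytest.approx(0.7 * e.asd_voxels)


def test_absent_structure_flagged():
    empty = np.zeros((8, 8, 8), bool)
    present = np.zeros_like(empty)
    present[2:4, 2:4, 2:4] = True
    grid = VolumeGrid.isotropic(8)
    a = LabelVolume(grid, np.zeros((8, 8, 8), int), {1: "s"})
    b = LabelVolume(grid, np.where(present, 1, 0), {1: "s"})
    e_both = overlap_metrics(a, LabelVolume(grid, np.zeros((8, 8, 8), int), {1: "s"}), 1)
    assert not e_both.defined
    e_one = overlap_metrics(a, b, 1)
    assert e_one.defined and e_one.dice == 0.0


def test_overlap_report_covers_union_of_tables():
    grid = VolumeGrid.isotropic(8)
    la = np.zeros((8, 8, 8), int)
    la[2:4, 2:4, 2:4] = 1
    lb = np.zeros_like(la)
    lb[5:7, 5:7, 5:7] = 2
    rep = overlap_report(LabelVolume(grid, la), LabelVolume(grid, lb))
    assert [e.structure_id for e in rep] == [1, 2]


def test_volume_bias_hand_values():
    assert volume_bias([(100.0, 100.0), (250.0, 250.0)]) == 0.0
    assert volume_bias([(110.0, 100.0), (90.0, 100.0)]) == pytest.approx(0.0)
    assert volume_bias([(120.0, 100.0)]) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        volume_bias([])
    with pytest.raises(ValueError):
        volume_bias([(1.0, 0.0)])
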