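"""Dice and average surface distance against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from neoseg import LabelVolume, asd, dice_score, extract_surface, mean_quality
from neoseg.metrics import EmptyMaskError


def brute_force_dice(mask_s, mask_t):
    s = set(map(tuple, np.argwhere(mask_s)))
    t = set(map(tuple, np.argwhere(mask_t)))
    if not s and not t:
        return 1.0
    return 2 * len(s & t) / (len(s) + len(t))


def brute_force_surface(mask):
    """All mask voxels with a face neighbour outside the mask or the grid."""
    pts = []
    for p in np.argwhere(mask):
        for ax in range(mask.ndim):
            for d in (-1, 1):
                q = p.copy()
                q[ax] += d
                if (q < 0).any() or (q >= np.array(mask.shape)).any() or not mask[tuple(q)]:
                    pts.append(tuple(p))
                    break
            else:
                continue
            break
    return np.array(sorted(set(pts)))


def brute_force_asd(mask_s, mask_t, spacing):
    rs = brute_force_surface(mask_s) * np.asarray(spacing)
    rt = brute_force_surface(mask_t) * np.asarray(spacing)
    d = cdist(rs, rt)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def _vol(mask, spacing=None):
    return LabelVolume(mask.astype(np.int64), spacing=spacing)


class TestDice:
    def test_perfect_overlap(self):
        m = np.zeros((4, 4), dtype=np.int64)
        m[1:3, 1:3] = 1
        assert dice_score(_vol(m), _vol(m), 1) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 5), dtype=np.int64)
        b = np.zeros((4, 5), dtype=np.int64)
        a[:2] = 1  # 10 voxels
        b[2:] = 1  # 10 voxels
        assert dice_score(_vol(a), _vol(b), 1) == 0.0

    def test_hand_evaluated_overlap(self):
        # |S| = 8, |T| = 8, |S∩T| = 6 on a 4x4 grid -> 2*6/16 = 0.75
        s = np.zeros((4, 4), dtype=np.int64)
        t = np.zeros((4, 4), dtype=np.int64)
        s[0:2, :] = 1
        t[0:2, 0:3] = 1
        t[2, 0:2] = 1
        assert int((s == 1).sum()) == 8 and int((t == 1).sum()) == 8
        assert int(((s == 1) & (t == 1)).sum()) == 6
        assert dice_score(_vol(s), _vol(t), 1) == pytest.approx(0.75, abs=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            dice_score(_vol(np.zeros((3, 3), dtype=np.int64)),
                       _vol(np.zeros((4, 4), dtype=np.int64)), 1)

    def test_absent_label_convention(self):
        z = _vol(np.zeros((3, 3), dtype=np.int64))
        assert dice_score(z, z, 5) == 1.0

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(50):
            shape = tuple(rng.integers(3, 7, size=rng.integers(2, 4)))
            a = rng.random(shape) < 0.4
            b = rng.random(shape) < 0.4
            got = dice_score(_vol(a), _vol(b), 1)
            want = brute_force_dice(a, b)
            assert got == pytest.approx(want, abs=1e-12)
            assert dice_score(_vol(a), _vol(b), 1) == dice_score(_vol(b), _vol(a), 1)


class TestSurface:
    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((5, 5, 5), dtype=np.int64)
        m[2, 2, 2] = 1
        surf = extract_surface(_vol(m), 1)
        assert len(surf) == 1 and tuple(surf.points[0]) == (2, 2, 2)

    def test_filled_cube_surface_count(self):
        m = np.zeros((7, 7, 7), dtype=np.int64)
        m[1:6, 1:6, 1:6] = 1
        assert len(extract_surface(_vol(m), 1)) == 98  # 5^3 - 3^3

    def test_thin_sheet_all_surface(self):
        m = np.zeros((6, 6, 6), dtype=np.int64)
        m[3] = 1
        assert len(extract_surface(_vol(m), 1)) == 36

    def test_grid_edge_counts_as_outside(self):
        # all voxels of a full 3x3 grid touch the grid edge except the centre,
        # whose face neighbours all lie inside the mask
        m = np.ones((3, 3), dtype=np.int64)
        surf = extract_surface(_vol(m), 1)
        assert len(surf) == 8
        assert (1, 1) not in set(map(tuple, surf.points))

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_surface(_vol(np.zeros((3, 3), dtype=np.int64)), 1)


class TestASD:
    def test_perfect_match_is_zero(self):
        m = np.zeros((6, 6, 6), dtype=np.int64)
        m[2:5, 2:5, 2:5] = 1
        assert asd(_vol(m), _vol(m), 1) == 0.0

    def test_parallel_sheets(self):
        # two 1-voxel sheets offset by 2 along axis 0 -> every distance is 2 mm
        a = np.zeros((8, 5, 5), dtype=np.int64)
        b = np.zeros((8, 5, 5), dtype=np.int64)
        a[2] = 1
        b[4] = 1
        assert asd(_vol(a), _vol(b), 1) == pytest.approx(2.0, abs=1e-12)

    def test_empty_side_raises(self):
        m = np.zeros((4, 4), dtype=np.int64)
        m[1, 1] = 1
        with pytest.raises(EmptyMaskError):
            asd(_vol(m), _vol(np.zeros((4, 4), dtype=np.int64)), 1)

    def _random_nonempty(self, rng, shape):
        while True:
            m = rng.random(shape) < 0.35
            if m.any():
                return m

    def test_matches_brute_force_and_is_symmetric(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(4, 9, size=3))
            a = self._random_nonempty(rng, shape)
            b = self._random_nonempty(rng, shape)
            got = asd(_vol(a), _vol(b), 1)
            want = brute_force_asd(a, b, (1.0, 1.0, 1.0))
            assert got == pytest.approx(want, abs=1e-9)
            assert asd(_vol(a), _vol(b), 1) == pytest.approx(
                asd(_vol(b), _vol(a), 1), abs=1e-12
            )

    def test_scales_linearly_with_spacing(self, rng):
        a = self._random_nonempty(rng, (6, 6, 6))
        b = self._random_nonempty(rng, (6, 6, 6))
        one = asd(_vol(a, (1.0, 1.0, 1.0)), _vol(b, (1.0, 1.0, 1.0)), 1)
        two = asd(_vol(a, (2.0, 2.0, 2.0)), _vol(b, (2.0, 2.0, 2.0)), 1)
        assert two == pytest.approx(2 * one, rel=1e-9)

    def test_anisotropic_spacing_matches_brute_force(self, rng):
        a = self._random_nonempty(rng, (5, 6, 4))
        b = self._random_nonempty(rng, (5, 6, 4))
        spacing = (1.0, 0.5, 2.0)
        got = asd(_vol(a, spacing), _vol(b, spacing), 1)
        assert got == pytest.approx(brute_force_asd(a, b, spacing), abs=1e-9)


class TestMeanQuality:
    def test_reported_tissue_average(self):
        # averaging per-tissue Dice {CSF 0.96, GM 0.9367, WM 0.9317} -> 0.9428
        assert np.mean([0.96, 0.9367, 0.9317]) == pytest.approx(0.9428, abs=1e-12)

    def test_is_unweighted_mean_of_per_label_dice(self, rng):
        pred = _vol(rng.integers(0, 4, size=(6, 6)))
        truth = _vol(rng.integers(0, 4, size=(6, 6)))
        per_label = [dice_score(pred, truth, lab) for lab in (1, 2, 3)]
        assert mean_quality(pred, truth, [1, 2, 3]) == pytest.approx(np.mean(per_label))
        assert mean_quality(pred, truth, [2]) == pytest.approx(per_label[1])

    def test_perfect_prediction(self):
        m = np.zeros((5, 5), dtype=np.int64)
        m[1:3] = 1
        m[3:] = 2
        assert mean_quality(_vol(m), _vol(m), [1, 2]) == 1.0

    def test_empty_label_list_rejected(self):
        z = _vol(np.zeros((3, 3), dtype=np.int64))
        with pytest.raises(ValueError):
            mean_quality(z, z, [])


class TestLabelVolume:
    def test_rejects_float_labels(self):
        with pytest.raises(ValueError):
            LabelVolume(np.zeros((3, 3)))

    def test_rejects_bad_spacing(self):
        with pytest.raises(ValueError):
            LabelVolume(np.zeros((3, 3), dtype=np.int64), spacing=(1.0,))
        with pytest.raises(ValueError):
            LabelVolume(np.zeros((3, 3), dtype=np.int64), spacing=(0.0, 1.0))
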