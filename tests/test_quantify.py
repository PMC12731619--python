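from itertools import permutations

import numpy as np
import pytest

from flyquant.io import IntensityImage
from flyquant.quantify import (
    area_fraction,
    colocalize,
    ctcf,
    method_agreement,
)
from flyquant.segmentation import label_objects


def _as_map(binary, connectivity=8):
    return label_objects(np.asarray(binary, dtype=bool), connectivity)


# ---------------------------------------------------------------------------
# area_fraction
# ---------------------------------------------------------------------------

class TestAreaFraction:
    def test_basic_percent(self):
        g = np.zeros((20, 20), dtype=bool)
        g[0:5, 0:6] = True  # 30 px inside ROI
        g[15, 15] = True    # outside ROI
        roi = np.zeros((20, 20), dtype=bool)
        roi[0:10, 0:20] = True  # 200 px
        q = area_fraction(_as_map(g), roi)
        assert q.roi_area_px == 200
        assert q.signal_area_px == 30
        assert q.area_percent == 15.0

    def test_no_signal(self):
        roi = np.ones((5, 5), dtype=bool)
        q = area_fraction(_as_map(np.zeros((5, 5))), roi)
        assert q.area_percent == 0.0

    def test_full_coverage(self):
        roi = np.ones((4, 4), dtype=bool)
        q = area_fraction(_as_map(np.ones((4, 4))), roi)
        assert q.area_percent == 100.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            area_fraction(_as_map(np.ones((4, 4))), np.zeros((4, 4), dtype=bool))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            area_fraction(_as_map(np.ones((4, 4))), np.ones((5, 5), dtype=bool))


# ---------------------------------------------------------------------------
# colocalize
# ---------------------------------------------------------------------------

class TestColocalize:
    def test_overlap_percent(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[0, 0:10] = True           # 10 px
        b[0, 2:6] = b[1, 0:4] = True  # 8 px, 4 overlapping
        roi = np.ones((10, 10), dtype=bool)
        c = colocalize(_as_map(a), _as_map(b), roi)
        assert c.overlap_area_px == 4
        assert c.overlap_percent_of_roi == 4.0

    def test_disjoint(self):
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[0, 0] = True
        b[5, 5] = True
        c = colocalize(_as_map(a), _as_map(b), np.ones((6, 6), dtype=bool))
        assert c.overlap_area_px == 0
        assert c.n_A_objects_colocalized == 0

    def test_partial_vs_total_on_6x6_scene(self):
        # object 1 fully inside B; object 2 half inside B
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[0, 0:2] = True            # object 1: 2 px
        a[3, 0:4] = True            # object 2: 4 px
        b[0, 0:3] = True            # covers object 1 entirely
        b[3, 0:2] = True            # covers half of object 2
        roi = np.ones((6, 6), dtype=bool)
        # exhaustive pixel check for the expected overlap
        expected_overlap = int((a & b & roi).sum())
        assert expected_overlap == 4
        part = colocalize(_as_map(a), _as_map(b), roi, mode="partial")
        tot = colocalize(_as_map(a), _as_map(b), roi, mode="total")
        assert part.overlap_area_px == tot.overlap_area_px == 4
        assert part.n_A_objects_colocalized == 2  # both touch B
        assert tot.n_A_objects_colocalized == 1   # only the contained one
        assert part.n_A_objects_total == tot.n_A_objects_total == 2

    def test_total_mode_clips_to_roi(self):
        # object extends outside ROI but its ROI part is inside B -> total yes
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[2, 0:6] = True
        b[2, 0:3] = True
        roi = np.zeros((6, 6), dtype=bool)
        roi[:, 0:3] = True
        tot = colocalize(_as_map(a), _as_map(b), roi, mode="total")
        assert tot.n_A_objects_colocalized == 1

    def test_symmetry_of_overlap_area(self, rng):
        for _ in range(25):
            a = rng.random((12, 12)) < 0.3
            b = rng.random((12, 12)) < 0.3
            roi = rng.random((12, 12)) < 0.8
            if not roi.any():
                continue
            ab = colocalize(_as_map(a), _as_map(b), roi)
            ba = colocalize(_as_map(b), _as_map(a), roi)
            assert ab.overlap_area_px == ba.overlap_area_px

    def test_overlap_bounded_by_single_signals(self, rng):
        for _ in range(25):
            a = rng.random((12, 12)) < 0.4
            b = rng.random((12, 12)) < 0.4
            roi = np.ones((12, 12), dtype=bool)
            c = colocalize(_as_map(a), _as_map(b), roi)
            qa = area_fraction(_as_map(a), roi)
            qb = area_fraction(_as_map(b), roi)
            assert c.overlap_percent_of_roi <= min(qa.area_percent, qb.area_percent)
            assert c.overlap_area_px <= min(qa.signal_area_px, qb.signal_area_px)


# ---------------------------------------------------------------------------
# ctcf
# ---------------------------------------------------------------------------

class TestCtcf:
    def test_formula(self):
        img = np.zeros((10, 10))
        cell = np.zeros((10, 10), dtype=bool)
        bg = np.zeros((10, 10), dtype=bool)
        cell[0:5, 0:10] = True  # 50 px
        img[cell] = 20.0        # integrated density 1000
        bg[9, :] = True
        img[bg] = 2.0
        r = ctcf(IntensityImage(img), cell, bg)
        assert r.integrated_density == 1000.0
        assert r.cell_area_px == 50
        assert r.background_mean == 2.0
        assert r.ctcf == 900.0

    def test_uniform_image_zero(self):
        img = IntensityImage(np.full((8, 8), 7.0))
        cell = np.zeros((8, 8), dtype=bool)
        bg = np.zeros((8, 8), dtype=bool)
        cell[0:4, :] = True
        bg[6:, :] = True
        assert ctcf(img, cell, bg).ctcf == pytest.approx(0.0)

    def test_zero_background(self):
        img = np.zeros((6, 6))
        cell = np.zeros((6, 6), dtype=bool)
        bg = np.zeros((6, 6), dtype=bool)
        cell[0:2, :] = True
        img[cell] = 5.0
        bg[5, :] = True
        r = ctcf(IntensityImage(img), cell, bg)
        assert r.ctcf == r.integrated_density

    def test_overlapping_masks_rejected(self):
        img = IntensityImage(np.ones((4, 4)))
        m = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            ctcf(img, m, m)

    def test_empty_mask_rejected(self):
        img = IntensityImage(np.ones((4, 4)))
        m = np.zeros((4, 4), dtype=bool)
        ok = np.zeros((4, 4), dtype=bool)
        ok[0, 0] = True
        with pytest.raises(ValueError, match="non-empty"):
            ctcf(img, m, ok)

    def test_constant_shift_invariance(self, rng):
        for _ in range(20):
            img = rng.random((10, 10)) * 100
            cell = rng.random((10, 10)) < 0.3
            bg = ~cell & (rng.random((10, 10)) < 0.3)
            if not cell.any() or not bg.any():
                continue
            c = float(rng.random() * 50)
            r0 = ctcf(IntensityImage(img), cell, bg)
            r1 = ctcf(IntensityImage(img + c), cell, bg)
            assert r1.ctcf == pytest.approx(r0.ctcf, abs=1e-6)


# ---------------------------------------------------------------------------
# method_agreement
# ---------------------------------------------------------------------------

def brute_force_max_matching(overlap_pairs, n_ref, n_aut):
    """Exhaustive maximum any-overlap matching for tiny object counts."""
    best = 0
    ref_ids = list(range(n_ref))
    for k in range(min(n_ref, n_aut), 0, -1):
        from itertools import combinations

        for refs in combinations(ref_ids, k):
            for auts in permutations(range(n_aut), k):
                if all((r, a) in overlap_pairs for r, a in zip(refs, auts)):
                    return k
    return best


class TestMethodAgreement:
    def test_identical_maps_all_matched(self, rng):
        g = rng.random((15, 15)) < 0.2
        om = _as_map(g)
        roi = np.ones((15, 15), dtype=bool)
        agree = method_agreement(om, om, roi)
        assert agree.n_matched == om.n_objects
        assert agree.n_only_reference == agree.n_only_automated == 0

    def test_extra_automated_object(self):
        ref = np.zeros((10, 10), dtype=bool)
        aut = np.zeros((10, 10), dtype=bool)
        ref[0:2, 0:2] = True
        aut[0:2, 0:2] = True
        aut[7:9, 7:9] = True
        agree = method_agreement(
            _as_map(ref), _as_map(aut), np.ones((10, 10), dtype=bool)
        )
        assert agree.n_matched == 1
        assert agree.n_only_automated == 1
        assert agree.n_only_reference == 0

    def test_matches_exhaustive_oracle(self, rng):
        roi = np.ones((14, 14), dtype=bool)
        for _ in range(40):
            ref = rng.random((14, 14)) < 0.25
            aut = rng.random((14, 14)) < 0.25
            rm, am = _as_map(ref), _as_map(aut)
            if rm.n_objects > 6 or am.n_objects > 6:
                continue
            pairs = set()
            for r in range(1, rm.n_objects + 1):
                for a in range(1, am.n_objects + 1):
                    if ((rm.labels == r) & (am.labels == a)).any():
                        pairs.add((r - 1, a - 1))
            want = brute_force_max_matching(pairs, rm.n_objects, am.n_objects)
            got = method_agreement(rm, am, roi)
            assert got.n_matched == want
            assert got.n_only_reference == rm.n_objects - want
            assert got.n_only_automated == am.n_objects - want

    def test_counts_additive(self, rng):
        g1 = rng.random((12, 12)) < 0.3
        g2 = rng.random((12, 12)) < 0.3
        agree = method_agreement(
            _as_map(g1), _as_map(g2), np.ones((12, 12), dtype=bool)
        )
        assert agree.n_matched + agree.n_only_reference == agree.n_objects_reference
        assert agree.n_matched + agree.n_only_automated == agree.n_objects_automated
        assert agree.n_matched <= min(
            agree.n_objects_reference, agree.n_objects_automated
        )
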