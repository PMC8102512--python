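"""Otsu binarization, IoU, agreement and missed-pathology scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage.filters import threshold_otsu as sk_threshold_otsu

from funduscam.saliency import SaliencyMap
from funduscam.scoring import (
    BinaryMap,
    IoURecord,
    binarize_otsu,
    iou,
    mean_iou_by_component,
    missed_pathology,
    otsu_threshold,
    pairwise_agreement,
    permutation_null_iou,
)


def exhaustive_otsu(values: np.ndarray, n_bins: int = 256) -> float:
    """Independent oracle: try every candidate edge, score the pixel
    partition's between-class variance directly."""
    v = np.asarray(values, dtype=np.float64).ravel()
    edges = np.linspace(0, 1, n_bins + 1)
    hist, _ = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    mids = (edges[:-1] + edges[1:]) / 2
    rep = np.repeat(mids, hist)  # bin-quantized pixel values
    best, best_thr = -1.0, edges[1]
    for k in range(n_bins - 1):
        thr = edges[k + 1]
        lo, hi = rep[rep <= thr], rep[rep > thr]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(rep), len(hi) / len(rep)
        sigma = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sigma > best + 1e-15:
            best, best_thr = sigma, thr
    return best_thr


class TestOtsu:
    def test_bimodal_map_splits_between_modes(self):
        values = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)])
        rng = np.random.default_rng(0)
        rng.shuffle(values)
        values = values.reshape(10, 10)
        b = binarize_otsu(SaliencyMap(values))
        assert 0.2 < b.threshold < 0.8
        assert np.array_equal(b.values, values > 0.5)

    def test_constant_map_yields_empty_detection(self):
        b = binarize_otsu(SaliencyMap(np.full((8, 8), 0.4)))
        assert not b.values.any()
        assert b.threshold == pytest.approx(0.4)

    def test_threshold_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            v = rng.beta(rng.uniform(0.5, 3), rng.uniform(0.5, 3), size=(16, 16))
            assert otsu_threshold(v) == pytest.approx(exhaustive_otsu(v), abs=1e-12)

    def test_close_to_reference_library_threshold(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = np.clip(rng.normal(0.4, 0.2, (32, 32)), 0, 1)
            assert abs(otsu_threshold(v) - sk_threshold_otsu(v, nbins=256)) < 0.01

    def test_affine_rescaling_preserves_selected_pixels(self):
        rng = np.random.default_rng(11)
        v = rng.choice([0.15, 0.45, 0.85], size=(12, 12), p=[0.4, 0.3, 0.3])
        sel = binarize_otsu(SaliencyMap(v)).values
        for a, b in [(0.5, 0.1), (0.8, 0.2), (0.3, 0.0)]:
            w = a * v + b
            sel_resc = binarize_otsu(SaliencyMap(w)).values
            assert np.array_equal(sel, sel_resc)
            assert binarize_otsu(SaliencyMap(w)).threshold == pytest.approx(
                exhaustive_otsu(w), abs=1e-12)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            otsu_threshold(np.array([0.5, 1.5]))


def naive_iou(a: np.ndarray, b: np.ndarray) -> float | None:
    inter = union = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if a[i, j] and b[i, j]:
                inter += 1
            if a[i, j] or b[i, j]:
                union += 1
    return None if union == 0 else inter / union


class TestIoU:
    def test_identical_nonempty_masks_score_one(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        assert iou(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = b[5, 5] = True
        assert iou(a, b) == 0.0

    def test_shifted_block_scores_one_third(self):
        a = np.zeros((4, 5), bool)
        b = np.zeros((4, 5), bool)
        a[1:3, 1:3] = True
        b[1:3, 2:4] = True  # overlap 2 px, union 6 px
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_undefined(self):
        z = np.zeros((4, 4), bool)
        assert iou(z, z) is None

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            iou(np.zeros((3, 3), bool), np.zeros((4, 4), bool))

    @given(hnp.arrays(bool, (16, 16)), hnp.arrays(bool, (16, 16)))
    @settings(max_examples=300, deadline=None)
    def test_matches_naive_pixel_loop(self, a, b):
        assert iou(a, b) == naive_iou(a, b)


class TestMeanIoU:
    def test_single_record_mean_is_its_score(self):
        out = mean_iou_by_component([IoURecord("i", "m", "vessels", 0.4)])
        assert out["mean_iou"].iloc[0] == pytest.approx(0.4)

    def test_zero_one_pair_averages_to_half(self):
        recs = [IoURecord("a", "m", "exudate", 0.0),
                IoURecord("b", "m", "exudate", 1.0)]
        assert mean_iou_by_component(recs)["mean_iou"].iloc[0] == pytest.approx(0.5)

    def test_undefined_scores_excluded_not_zeroed(self):
        recs = [IoURecord("a", "m", "exudate", None),
                IoURecord("b", "m", "exudate", 0.6),
                IoURecord("c", "m", "hemorrhage", None)]
        out = mean_iou_by_component(recs).set_index("component")
        assert out.loc["exudate", "mean_iou"] == pytest.approx(0.6)
        assert out.loc["exudate", "n_defined"] == 1
        assert out.loc["exudate", "n_total"] == 2
        assert np.isnan(out.loc["hemorrhage", "mean_iou"])


class TestAgreement:
    @staticmethod
    def _maps():
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:4] = True
        b[2:6] = True  # IoU = 2/6
        return {"m1": [BinaryMap(a)], "m2": [BinaryMap(b)]}

    def test_self_agreement_is_unity(self):
        m = self._maps()
        mat = pairwise_agreement({"m1": m["m1"], "m1b": m["m1"]})
        assert np.allclose(np.diag(mat.values), 1.0)
        assert mat.loc["m1", "m1b"] == 1.0

    def test_symmetric_with_known_overlap(self):
        mat = pairwise_agreement(self._maps())
        assert mat.loc["m1", "m2"] == pytest.approx(1 / 3)
        assert np.array_equal(mat.values, mat.values.T)

    def test_component_stratified_variant(self):
        m = self._maps()
        comp = np.zeros((8, 8), bool)
        comp[:2] = True  # restrict to top strip: m1 covers it, m2 misses it
        mat = pairwise_agreement(m, component_masks=[comp])
        assert mat.loc["m1", "m2"] == 0.0

    def test_mismatched_image_sets_rejected(self):
        m = self._maps()
        m["m2"] = m["m2"] + m["m2"]
        with pytest.raises(ValueError, match="image sets"):
            pairwise_agreement(m)


class TestMissedPathology:
    @staticmethod
    def _five_lesions():
        masks = np.zeros((20, 20), bool)
        for k in range(5):
            masks[4 * k : 4 * k + 2, 0:2] = True  # 5 separated 2x2 lesions
        return {"hemorrhage": masks}

    def test_full_coverage_misses_nothing(self):
        det = BinaryMap(np.ones((20, 20), bool))
        rec = missed_pathology(det, self._five_lesions())
        assert rec.lesions_total == 5
        assert rec.percent_missed == 0.0

    def test_empty_detection_misses_everything(self):
        rec = missed_pathology(BinaryMap(np.zeros((20, 20), bool)),
                               self._five_lesions())
        assert rec.percent_missed == 100.0
        assert rec.percent_pixels_missed == 100.0

    def test_partial_overlap_counts_lesions(self):
        det = np.zeros((20, 20), bool)
        det[0:10, :] = True  # covers lesions at rows 0,4,8 -> 3 of 5
        rec = missed_pathology(BinaryMap(det), self._five_lesions())
        assert rec.lesions_missed == 2
        assert rec.percent_missed == pytest.approx(40.0)

    def test_strict_tau_requires_area_fraction(self):
        det = np.zeros((20, 20), bool)
        det[0, 0] = True  # 1 of 4 px of the first lesion
        rec_loose = missed_pathology(BinaryMap(det), self._five_lesions(), tau=0.0)
        rec_strict = missed_pathology(BinaryMap(det), self._five_lesions(), tau=0.5)
        assert rec_loose.lesions_missed == 4
        assert rec_strict.lesions_missed == 5

    def test_no_lesions_reports_undefined_percent(self):
        rec = missed_pathology(BinaryMap(np.zeros((8, 8), bool)),
                               {"hemorrhage": np.zeros((8, 8), bool)})
        assert rec.lesions_total == 0
        assert rec.percent_missed is None

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_growing_detection_never_increases_missed(self, seed):
        rng = np.random.default_rng(seed)
        lesions = {"hemorrhage": rng.uniform(size=(16, 16)) < 0.15}
        det = rng.uniform(size=(16, 16)) < 0.2
        grown = det | (rng.uniform(size=(16, 16)) < 0.3)
        a = missed_pathology(BinaryMap(det), lesions)
        b = missed_pathology(BinaryMap(grown), lesions)
        assert b.lesions_missed <= a.lesions_missed


def test_permutation_null_detects_aligned_detection():
    """A detection sitting exactly on the mask beats every random placement."""
    rng = np.random.default_rng(0)
    fov = np.zeros((32, 32), bool)
    yy, xx = np.mgrid[0:32, 0:32]
    fov[(yy - 15.5) ** 2 + (xx - 15.5) ** 2 < 15**2] = True
    masks, dets = [], []
    for _ in range(6):
        m = np.zeros((32, 32), bool)
        r, c = rng.integers(8, 22, 2)
        m[r : r + 3, c : c + 3] = True
        m &= fov
        masks.append(m)
        dets.append(BinaryMap(m.copy()))
    obs, null, p = permutation_null_iou(dets, masks, [fov] * 6,
                                        n_permutations=49, seed=1)
    assert obs == 1.0
    assert p <= 1 / 50 + 1e-9
    assert null.max() < 1.0
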