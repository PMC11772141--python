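import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myofiber_morph import (MatchObject, binned_histogram, fp_fn_rates,
                            match_objects, paired_regression,
                            percent_accuracy)
from myofiber_morph.validation import Matching


class TestPercentAccuracy:
    @pytest.mark.parametrize("manual,auto,expected", [
        (100, 96, 96.0),
        (100, 100, 100.0),
        (100, 104, 96.0),  # symmetric in the sign of the disagreement
    ])
    def test_examples(self, manual, auto, expected):
        assert percent_accuracy(manual, auto) == expected

    def test_zero_manual_undefined(self):
        with pytest.raises(ValueError):
            percent_accuracy(0, 5)


def _objs(centroids, masks=None):
    out = []
    for i, c in enumerate(centroids):
        out.append(MatchObject(centroid=c,
                               mask=None if masks is None else masks[i]))
    return out


class TestMatching:
    def test_identical_lists_fully_matched(self):
        pts = [(5.0, 5.0), (20.0, 20.0), (40.0, 10.0)]
        m = match_objects(_objs(pts), _objs(pts))
        assert len(m.pairs) == 3
        assert m.unmatched_ref == [] and m.unmatched_det == []

    def test_extra_detection_is_unmatched(self):
        ref = _objs([(5.0, 5.0), (20.0, 20.0)])
        det = _objs([(5.0, 5.0), (20.0, 20.0), (90.0, 90.0)])
        m = match_objects(ref, det)
        assert len(m.pairs) == 2
        assert m.unmatched_det == [2]

    def test_greedy_equals_exhaustive_when_unambiguous(self):
        # brute-force optimal one-to-one assignment as independent oracle
        rng = np.random.default_rng(42)
        shape = (60, 60)
        ref_masks, det_masks = [], []
        for k in range(6):
            r, c = 10 * (k // 3) * 2 + 8, 18 * (k % 3) + 8
            m = np.zeros(shape, bool)
            m[r:r + 8, c:c + 8] = True
            ref_masks.append(m)
            d = np.roll(m, shift=(int(rng.integers(-1, 2)),
                                  int(rng.integers(-1, 2))), axis=(0, 1))
            det_masks.append(d)
        order = rng.permutation(6)
        det_masks = [det_masks[i] for i in order]
        cent = lambda m: tuple(np.argwhere(m).mean(axis=0))
        ref = _objs([cent(m) for m in ref_masks], ref_masks)
        det = _objs([cent(m) for m in det_masks], det_masks)

        def iou(a, b):
            inter = (a & b).sum()
            return inter / (a | b).sum() if inter else 0.0

        best, best_pairs = -1.0, None
        for perm in itertools.permutations(range(6)):
            total = sum(iou(ref_masks[i], det_masks[perm[i]])
                        for i in range(6))
            if total > best:
                best, best_pairs = total, {(i, perm[i]) for i in range(6)}
        m = match_objects(ref, det)
        # all IoUs here exceed 0.5, so greedy must equal the optimum
        assert set(m.pairs) == best_pairs


class TestRates:
    def test_paper_style_example(self):
        m = Matching(pairs=[(i, i) for i in range(95)],
                     unmatched_ref=list(range(95, 100)),
                     unmatched_det=list(range(95, 100)))
        assert fp_fn_rates(m, 100) == (5.0, 5.0)

    def test_perfect_detection(self):
        m = Matching(pairs=[(0, 0)], unmatched_ref=[], unmatched_det=[])
        assert fp_fn_rates(m, 1) == (0.0, 0.0)

    def test_missed_only(self):
        m = Matching(pairs=[(i, i) for i in range(90)],
                     unmatched_ref=list(range(90, 100)), unmatched_det=[])
        assert fp_fn_rates(m, 100) == (0.0, 10.0)

    def test_zero_reference_error(self):
        with pytest.raises(ValueError):
            fp_fn_rates(Matching(), 0)


class TestRegression:
    def test_identity_line(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        slope, intercept, r2 = paired_regression(x, x)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_affine_line(self):
        x = np.arange(1.0, 8.0)
        slope, intercept, r2 = paired_regression(x, 2 * x + 3)
        assert (slope, intercept) == (pytest.approx(2.0), pytest.approx(3.0))
        assert r2 == pytest.approx(1.0)

    def test_independent_pairs_have_near_zero_r2(self):
        rng = np.random.default_rng(2024)
        x = rng.normal(size=200)
        y = rng.permutation(rng.normal(size=200))
        _, _, r2 = paired_regression(x, y)
        assert r2 < 0.05

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            paired_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestHistogram:
    def test_csa_bin_example(self):
        counts, edges = binned_histogram([100, 250, 650], 300.0)
        assert counts.tolist() == [2, 0, 1]
        assert edges[0] == 0.0 and edges[1] == 300.0

    def test_empty_input(self):
        counts, _ = binned_histogram([], 15.0)
        assert counts.sum() == 0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            binned_histogram([-1.0], 300.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e4,
                              allow_nan=False), max_size=60),
           st.floats(min_value=0.5, max_value=500))
    def test_counts_always_conserved(self, values, width):
        counts, _ = binned_histogram(values, width)
        assert counts.sum() == len(values)
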