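"""Detection matching and metrics: printed-count worked examples and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneuseg.evaluation import (
    DetectionResult,
    connected_components,
    dsc,
    f1,
    fps_per_scan,
    match_detections,
    merge_results,
    pearson_volume_correlation,
    precision,
    round_half_away,
    sensitivity,
    volume_binned_report,
)
from aneuseg.volume import Volume3D


def mask3d(arr, spacing=(0.5, 0.5, 0.5)):
    return Volume3D(np.asarray(arr, dtype=np.uint8), spacing)


class TestComponents:
    def test_empty(self):
        assert connected_components(mask3d(np.zeros((5, 5, 5)))) == []

    def test_two_cubes(self):
        arr = np.zeros((10, 10, 10))
        arr[0:2, 0:2, 0:2] = 1
        arr[6:8, 6:8, 6:8] = 1
        comps = connected_components(mask3d(arr))
        assert len(comps) == 2
        assert all(c[2] == pytest.approx(1.0) for c in comps)  # 8 × 0.125 mm³

    def test_diagonal_pair_is_one_component_at_26(self):
        arr = np.zeros((4, 4, 4))
        arr[1, 1, 1] = 1
        arr[2, 2, 2] = 1
        assert len(connected_components(mask3d(arr), connectivity=26)) == 1
        assert len(connected_components(mask3d(arr), connectivity=6)) == 2


def brute_force_match(pred, ref):
    """Exhaustive set-based matching oracle: label via flood fill on voxel
    sets, attribute each predicted component to the reference it overlaps
    most, count TP/FP/FN."""
    from scipy import ndimage

    s = np.ones((3, 3, 3))
    pl, n_p = ndimage.label(pred, structure=s)
    rl, n_r = ndimage.label(ref, structure=s)
    pred_sets = [set(map(tuple, np.argwhere(pl == i))) for i in range(1, n_p + 1)]
    ref_sets = [set(map(tuple, np.argwhere(rl == i))) for i in range(1, n_r + 1)]
    assigned = {}
    fp = 0
    for pi, ps in enumerate(pred_sets):
        overlaps = [len(ps & rs) for rs in ref_sets]
        if not overlaps or max(overlaps) == 0:
            fp += 1
        else:
            assigned.setdefault(int(np.argmax(overlaps)), []).append(pi)
    tp = sum(1 for ri in range(n_r) if ri in assigned)
    fn = n_r - tp
    dscs = {}
    for ri, pis in assigned.items():
        union = set().union(*(pred_sets[pi] for pi in pis))
        inter = len(union & ref_sets[ri])
        dscs[ri] = 2 * inter / (len(union) + len(ref_sets[ri]))
    return tp, fp, fn, dscs


class TestMatching:
    def test_perfect_prediction(self):
        arr = np.zeros((10, 10, 10))
        arr[1:3, 1:3, 1:3] = 1
        arr[6:9, 6:9, 6:9] = 1
        r = match_detections(mask3d(arr), mask3d(arr))
        assert (r.tp, r.fp, r.fn) == (2, 0, 0)
        assert all(m.pair_dsc == 1.0 for m in r.matched)

    def test_empty_prediction(self):
        ref = np.zeros((10, 10, 10))
        ref[0:2, 0:2, 0:2] = 1
        ref[4:6, 4:6, 4:6] = 1
        ref[8:10, 8:10, 8:10] = 1
        r = match_detections(mask3d(np.zeros_like(ref)), mask3d(ref))
        assert (r.tp, r.fp, r.fn) == (0, 0, 3)

    def test_overlapping_plus_distant_blob(self):
        ref = np.zeros((10, 10, 10))
        ref[2:5, 2:5, 2:5] = 1
        pred = np.zeros_like(ref)
        pred[3:6, 3:6, 3:6] = 1  # overlaps
        pred[7:9, 7:9, 0:2] = 1  # distant
        r = match_detections(mask3d(pred), mask3d(ref))
        tp, fp, fn, dscs = brute_force_match(pred.astype(bool), ref.astype(bool))
        assert (r.tp, r.fp, r.fn) == (tp, fp, fn) == (1, 1, 0)
        assert r.matched[0].pair_dsc == pytest.approx(dscs[0])

    @pytest.mark.parametrize("seed", range(25))
    def test_randomized_equivalence_with_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((10, 10, 10)) < rng.uniform(0.02, 0.2)
        ref = rng.random((10, 10, 10)) < rng.uniform(0.02, 0.2)
        r = match_detections(mask3d(pred), mask3d(ref))
        tp, fp, fn, dscs = brute_force_match(pred, ref)
        assert (r.tp, r.fp, r.fn) == (tp, fp, fn)
        got = sorted(m.pair_dsc for m in r.matched)
        want = sorted(dscs.values())
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="common grid"):
            match_detections(mask3d(np.zeros((4, 4, 4))), mask3d(np.zeros((5, 4, 4))))


class TestPrintedCountExamples:
    """Detection metrics recomputed from published per-cohort TP/FP/FN counts."""

    @pytest.mark.parametrize(
        "tp,fn,expected", [(148, 23, 87), (57, 22, 72), (0, 5, 0)]
    )
    def test_sensitivity(self, tp, fn, expected):
        assert round_half_away(sensitivity(tp, fn)) == expected

    @pytest.mark.parametrize(
        "tp,fp,expected", [(178, 149, 54), (57, 14, 80), (7, 0, 100)]
    )
    def test_precision(self, tp, fp, expected):
        assert round_half_away(precision(tp, fp)) == expected

    @pytest.mark.parametrize(
        "tp,fn,fp,expected", [(178, 37, 149, 0.66), (57, 22, 14, 0.76)]
    )
    def test_f1_from_counts(self, tp, fn, fp, expected):
        value = f1(sensitivity(tp, fn), precision(tp, fp))
        assert round_half_away(value, 2) == expected

    @pytest.mark.parametrize(
        "fp,n,expected", [(26, 185, 0.14), (14, 68, 0.21), (0, 10, 0.0)]
    )
    def test_fps_per_scan(self, fp, n, expected):
        assert round_half_away(fps_per_scan(fp, n), 2) == expected

    def test_undefined_cases_rejected(self):
        with pytest.raises(ValueError):
            sensitivity(0, 0)
        with pytest.raises(ValueError):
            precision(0, 0)
        with pytest.raises(ValueError):
            fps_per_scan(1, 0)


class TestF1Properties:
    @given(st.floats(min_value=0.5, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_equal_inputs_identity(self, p):
        assert f1(p, p) == pytest.approx(p / 100.0)

    def test_both_zero_convention(self):
        assert f1(0.0, 0.0) == 0.0


class TestDsc:
    def test_identity_disjoint_and_partial(self):
        a = np.zeros((4, 4, 4))
        a[0:2, 0:2, 0:1] = 1
        b = np.zeros_like(a)
        b[0:2, 0:2, 1:2] = 1
        assert dsc(mask3d(a), mask3d(a)) == 1.0
        assert dsc(mask3d(a), mask3d(b)) == 0.0
        c = np.zeros_like(a)
        c[0:2, 0:2, 0:1] = 1
        c[0, 0, 0] = 0
        c[3, 3, 3] = 1
        # |a|=4, |c|=4, overlap 3 -> 0.75
        assert dsc(mask3d(a), mask3d(c)) == 0.75

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = mask3d(rng.random((6, 6, 6)) < 0.3)
        b = mask3d(rng.random((6, 6, 6)) < 0.3)
        assert dsc(a, b) == dsc(b, a)

    def test_empty_pair_rejected(self):
        z = mask3d(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            dsc(z, z)


class TestPearson:
    def test_exact_and_scaled_and_negative(self):
        ref = [10.0, 50.0, 200.0, 400.0]
        assert pearson_volume_correlation(ref, ref) == pytest.approx(1.0)
        assert pearson_volume_correlation(ref, [2 * v for v in ref]) == pytest.approx(1.0)
        assert pearson_volume_correlation(ref, [-v + 500 for v in ref]) == pytest.approx(-1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            pearson_volume_correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            pearson_volume_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBinnedReport:
    def _toy_result(self):
        from aneuseg.evaluation import MatchedPair

        matched = [
            MatchedPair(1, [1], 0.9, ref_volume_mm3=120.0, pred_volume_mm3=110.0),
            MatchedPair(2, [2], 0.7, ref_volume_mm3=40.0, pred_volume_mm3=35.0),
            MatchedPair(3, [3], 0.6, ref_volume_mm3=20.0, pred_volume_mm3=25.0),
        ]
        fn = [(4, 25.0), (5, 60.0)]
        fp = [(9, 10.0), (10, 80.0)]
        return DetectionResult(matched=matched, fn_components=fn, fp_components=fp, n_scans=4)

    def test_stratum_counts_match_hand_filter(self):
        reports = volume_binned_report(self._toy_result(), bins=(30.0, 100.0))
        by = {r.stratum: r for r in reports}
        assert (by["all"].tp, by["all"].fp, by["all"].fn) == (3, 2, 2)
        # >30: refs {120, 40, 60(FN)}; FPs with own volume >30: {80}
        assert (by[">30 mm³"].tp, by[">30 mm³"].fp, by[">30 mm³"].fn) == (2, 1, 1)
        # >100: refs {120}; FP volumes over 100: none
        assert (by[">100 mm³"].tp, by[">100 mm³"].fp, by[">100 mm³"].fn) == (1, 0, 0)

    def test_empty_stratum_absent(self):
        reports = volume_binned_report(self._toy_result(), bins=(1000.0,))
        assert [r.stratum for r in reports] == ["all"]

    def test_single_stratum_equals_unstratified(self):
        reports = volume_binned_report(self._toy_result(), bins=(0.0,))
        assert reports[0].to_dict() | {"stratum": ""} == reports[1].to_dict() | {"stratum": ""}

    def test_tp_plus_fn_is_reference_count(self):
        res = self._toy_result()
        for rep in volume_binned_report(res, bins=(30.0, 50.0)):
            assert rep.tp + rep.fn <= res.tp + res.fn
            assert rep.tp + rep.fn > 0

    def test_merge_results_pools_counts(self):
        r = self._toy_result()
        merged = merge_results([r, r])
        assert merged.tp == 2 * r.tp and merged.n_scans == 8


class TestRounding:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(0.5, 0, 1.0), (1.5, 0, 2.0), (2.5, 0, 3.0), (-0.5, 0, -1.0), (0.125, 2, 0.13),
         (82.79, 0, 83.0)],
    )
    def test_half_away_from_zero(self, value, decimals, expected):
        assert round_half_away(value, decimals) == expected
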