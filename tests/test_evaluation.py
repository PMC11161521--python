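import numpy as np
import pytest
from hypothesis import given, strategies as st

from pearpollen import (
    BACKGROUND,
    Box,
    Detection,
    FloweringStage,
    StageCounts,
    accuracy_rate_pct,
    confusion_with_background,
    corrected_error_pct,
    estimation_error_from_pollen,
    estimation_error_pct,
    iou,
    map50,
    stage_percentage_errors,
    stage_percentages,
)

E, B, L, TL, O = FloweringStage


class TestEstimationError:
    def test_worked_example_counts(self):
        assert estimation_error_pct(42, 62) == pytest.approx(-32.258, abs=1e-3)

    def test_perfect_detection(self):
        assert estimation_error_pct(57, 57) == 0.0

    def test_nothing_detected(self):
        assert estimation_error_pct(0, 30) == -100.0

    def test_undefined_for_zero_actual(self):
        with pytest.raises(ValueError):
            estimation_error_pct(5, 0)

    def test_pollen_form_agrees_when_proportions_match(self, chojuro):
        from pearpollen import estimate_pollen

        half = StageCounts.from_sequence([6, 4, 8, 2, 0])
        full = StageCounts.from_sequence([12, 8, 16, 4, 0])
        count_form = estimation_error_pct(half.total, full.total)
        pollen_form = estimation_error_from_pollen(
            estimate_pollen(half, chojuro).total_mg,
            estimate_pollen(full, chojuro).total_mg,
        )
        assert pollen_form == pytest.approx(count_form)

    def test_pollen_form_differs_when_proportions_differ(self, chojuro):
        from pearpollen import estimate_pollen

        detected = StageCounts.from_sequence([0, 10, 0, 0, 0])   # all Best
        actual = StageCounts.from_sequence([20, 0, 0, 0, 0])     # all Early
        count_form = estimation_error_pct(10, 20)
        pollen_form = estimation_error_from_pollen(
            estimate_pollen(detected, chojuro).total_mg,
            estimate_pollen(actual, chojuro).total_mg,
        )
        assert pollen_form != pytest.approx(count_form)


class TestCorrectedError:
    @pytest.mark.parametrize(
        "factor, expected", [(1.25, -2.89), (1.125, -15.39), (1.0, -27.89)]
    )
    def test_published_endpoints(self, factor, expected):
        assert corrected_error_pct(-27.89, factor) == pytest.approx(expected)

    @given(n_detected=st.integers(1, 500), n_actual=st.integers(1, 500))
    def test_multiplicative_mass_correction_zeroed_by_reciprocal_factor(
        self, n_detected, n_actual
    ):
        # on the mass ratio, factor n_actual/n_detected cancels the error exactly
        if n_detected > n_actual:
            n_detected, n_actual = n_actual, n_detected
        corrected_ratio_error = estimation_error_from_pollen(
            n_detected * (n_actual / n_detected), n_actual
        )
        assert corrected_ratio_error == pytest.approx(0.0, abs=1e-9)

    @given(n_detected=st.integers(1, 500), n_actual=st.integers(1, 500))
    def test_additive_form_zeroed_at_two_minus_ratio(self, n_detected, n_actual):
        # the additive percentage-point form instead zeroes at f = 2 - d/a
        if n_detected > n_actual:
            n_detected, n_actual = n_actual, n_detected
        error = estimation_error_pct(n_detected, n_actual)
        factor = 2.0 - n_detected / n_actual
        assert corrected_error_pct(error, factor) == pytest.approx(0.0, abs=1e-9)

    def test_shrinking_factor_rejected(self):
        with pytest.raises(ValueError):
            corrected_error_pct(-10.0, 0.5)


class TestAccuracyRate:
    @pytest.mark.parametrize(
        "correct, detected, expected",
        [(10, 10, 100.0), (32, 39, 82.051), (0, 7, 0.0)],
    )
    def test_values(self, correct, detected, expected):
        assert accuracy_rate_pct(correct, detected) == pytest.approx(expected, abs=1e-3)

    def test_undefined_for_zero_detections(self):
        with pytest.raises(ValueError):
            accuracy_rate_pct(0, 0)

    def test_more_correct_than_detected_rejected(self):
        with pytest.raises(ValueError):
            accuracy_rate_pct(5, 3)


class TestStagePercentages:
    def test_estimated_column(self, detected_counts):
        pct = stage_percentages(detected_counts)
        assert [pct.pct[s] for s in FloweringStage] == [31.0, 21.4, 38.1, 7.1, 2.4]

    def test_actual_column(self, actual_counts):
        pct = stage_percentages(actual_counts)
        assert [pct.pct[s] for s in FloweringStage] == [30.6, 21.0, 45.2, 3.2, 0.0]

    def test_single_stage(self):
        pct = stage_percentages(StageCounts({B: 9}))
        assert pct.pct[B] == 100.0

    def test_rounded_percentages_sum_near_100(self, detected_counts):
        assert sum(stage_percentages(detected_counts).pct.values()) == pytest.approx(
            100.0, abs=0.3
        )

    def test_undefined_for_empty_counts(self):
        with pytest.raises(ValueError):
            stage_percentages(StageCounts({}))

    def test_error_row(self, detected_counts, actual_counts):
        errors = stage_percentage_errors(
            stage_percentages(detected_counts), stage_percentages(actual_counts)
        )
        assert [errors[s] for s in FloweringStage] == [0.4, 0.4, -7.1, 3.9, 2.4]

    def test_error_row_zero_for_identical_input(self, detected_counts):
        pct = stage_percentages(detected_counts)
        assert all(v == 0.0 for v in stage_percentage_errors(pct, pct).values())


# ---------------------------------------------------------------------------
# confusion with background
# ---------------------------------------------------------------------------

def greedy_confusion_oracle(truth, detections, iou_threshold):
    """Second implementation of greedy IoU matching using a dense matrix."""
    n_t, n_d = len(truth), len(detections)
    mat = np.zeros((n_t, n_d))
    for i, (_, t_box) in enumerate(truth):
        for j, det in enumerate(detections):
            mat[i, j] = iou(t_box, det.box)
    counts = np.zeros((6, 6), dtype=int)
    free_t, free_d = set(range(n_t)), set(range(n_d))
    while True:
        best = None
        for i in sorted(free_t):
            for j in sorted(free_d):
                if mat[i, j] >= iou_threshold and mat[i, j] > 0:
                    if best is None or mat[i, j] > mat[best]:
                        best = (i, j)
        if best is None:
            break
        i, j = best
        counts[int(truth[i][0]), int(detections[j].stage)] += 1
        free_t.discard(i)
        free_d.discard(j)
    for i in free_t:
        counts[int(truth[i][0]), 5] += 1
    for j in free_d:
        counts[5, int(detections[j].stage)] += 1
    return counts


def small_instances():
    box = st.builds(
        lambda x, y, w, h: Box(x, y, x + w, y + h),
        st.integers(0, 40), st.integers(0, 40),
        st.integers(5, 30), st.integers(5, 30),
    )
    stage = st.sampled_from(list(FloweringStage))
    truth = st.lists(st.tuples(stage, box), max_size=6)
    dets = st.lists(
        st.builds(Detection, stage=stage,
                  confidence=st.floats(0.3, 1.0, allow_nan=False), box=box),
        max_size=6,
    )
    return st.tuples(truth, dets)


class TestConfusionWithBackground:
    def _identity_scene(self):
        boxes = [Box(40 * i, 10, 40 * i + 30, 40) for i in range(5)]
        truth = [(s, b) for s, b in zip(FloweringStage, boxes)]
        dets = [Detection(s, 0.9, b) for s, b in truth]
        return truth, dets

    def test_identity_when_detections_equal_truth(self):
        truth, dets = self._identity_scene()
        cm = confusion_with_background(truth, dets, 0.5)
        assert np.array_equal(cm.counts[:5, :5], np.eye(5, dtype=int))
        assert cm.counts[:, 5].sum() == 0 and cm.counts[5, :].sum() == 0

    def test_no_detections_puts_truth_in_background_column(self):
        truth, _ = self._identity_scene()
        cm = confusion_with_background(truth, [], 0.5)
        assert cm.counts[:5, 5].sum() == 5
        assert cm.counts[:5, :5].sum() == 0

    def test_spurious_detection_lands_in_background_row(self):
        truth, dets = self._identity_scene()
        extra = Detection(B, 0.8, Box(500, 500, 540, 540))
        cm = confusion_with_background(truth, dets + [extra], 0.5)
        assert cm[BACKGROUND, B] == 1

    def test_mislabel_counted_off_diagonal(self):
        truth = [(L, Box(0, 0, 30, 30))]
        dets = [Detection(TL, 0.9, Box(1, 1, 30, 30))]
        cm = confusion_with_background(truth, dets, 0.5)
        assert cm[L, TL] == 1

    def test_rows_sum_to_truth_counts(self):
        truth, dets = self._identity_scene()
        cm = confusion_with_background(truth, dets[:3], 0.5)
        assert cm.counts[:5, :].sum() == len(truth)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            confusion_with_background([], [], 1.5)

    @given(instance=small_instances())
    def test_matches_independent_greedy_oracle(self, instance):
        truth, dets = instance
        cm = confusion_with_background(truth, dets, 0.5)
        assert np.array_equal(cm.counts, greedy_confusion_oracle(truth, dets, 0.5))

    @given(instance=small_instances())
    def test_matched_pairs_bounded(self, instance):
        truth, dets = instance
        cm = confusion_with_background(truth, dets, 0.5)
        assert cm.counts[:5, :5].sum() <= min(len(truth), len(dets))


# ---------------------------------------------------------------------------
# mAP50
# ---------------------------------------------------------------------------

class TestMap50:
    def _truth(self):
        return [
            (E, Box(0, 0, 30, 30)),
            (E, Box(100, 100, 140, 140)),
            (B, Box(200, 200, 240, 240)),
        ]

    def test_perfect_detections(self):
        truth = self._truth()
        dets = [Detection(s, 1.0, b) for s, b in truth]
        assert map50(truth, dets) == 1.0

    def test_zero_detections(self):
        assert map50(self._truth(), []) == 0.0

    def test_three_box_hand_enumerated_ap(self):
        # one class, 2 truth boxes; TP(conf .9), FP(conf .8), TP(conf .7)
        # PR points: (0.5, 1), (0.5, 0.5), (1, 2/3)
        # all-point AP = 0.5*1 + 0.5*(2/3) = 5/6
        truth = [(E, Box(0, 0, 30, 30)), (E, Box(100, 100, 130, 130))]
        dets = [
            Detection(E, 0.9, Box(0, 0, 30, 30)),
            Detection(E, 0.8, Box(300, 300, 330, 330)),
            Detection(E, 0.7, Box(100, 100, 130, 130)),
        ]
        assert map50(truth, dets) == pytest.approx(5 / 6)

    def test_101_point_variant_on_hand_case(self):
        truth = [(E, Box(0, 0, 30, 30)), (E, Box(100, 100, 130, 130))]
        dets = [
            Detection(E, 0.9, Box(0, 0, 30, 30)),
            Detection(E, 0.8, Box(300, 300, 330, 330)),
            Detection(E, 0.7, Box(100, 100, 130, 130)),
        ]
        # grid points with recall<=0.5 interpolate to 1, the rest to 2/3
        expected = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert map50(truth, dets, interpolation="101point") == pytest.approx(expected)

    def test_duplicate_detections_of_one_truth_count_once(self):
        truth = [(E, Box(0, 0, 30, 30))]
        dets = [
            Detection(E, 0.9, Box(0, 0, 30, 30)),
            Detection(E, 0.8, Box(1, 1, 31, 31)),
        ]
        # second match is a false positive: AP = 1.0 (recall reaches 1 at rank 1)
        assert map50(truth, dets) == pytest.approx(1.0)

    def test_confidence_rescaling_invariance(self):
        truth = self._truth()
        dets = [
            Detection(E, 0.9, Box(0, 0, 30, 30)),
            Detection(E, 0.6, Box(500, 0, 530, 30)),
            Detection(B, 0.8, Box(200, 200, 240, 240)),
        ]
        scaled = [
            Detection(d.stage, d.confidence * 0.5, d.box) for d in dets
        ]
        assert map50(truth, dets) == pytest.approx(map50(truth, scaled))

    def test_requires_truth(self):
        with pytest.raises(ValueError):
            map50([], [])

    def test_requires_confidences(self):
        truth = self._truth()
        with pytest.raises(ValueError, match="confidence"):
            map50(truth, [Detection(E, None, Box(0, 0, 30, 30))])

    def test_images_kept_separate(self):
        # same geometry, different image: no cross-image matching
        t = [Detection(E, None, Box(0, 0, 30, 30), image_id="a")]
        d = [Detection(E, 0.9, Box(0, 0, 30, 30), image_id="b")]
        assert map50(t, d) == 0.0
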