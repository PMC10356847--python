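import itertools

import numpy as np
import pytest

from deepcenterline.detections import Detection
from deepcenterline.metrics import (
    EvalConfig, adtw, integrity_over_dataset, match_labels_to_predictions,
    point_segment_distance, tp_fn_rates, tracking_integrity,
)
from deepcenterline.tracking import Track


class TestPointSegmentDistance:
    def test_point_on_segment_zero(self):
        d = point_segment_distance(np.array([[0.5, 0.0]]),
                                   np.array([[0.0, 0.0]]),
                                   np.array([[1.0, 0.0]]))
        assert d[0, 0] == pytest.approx(0.0)

    def test_perpendicular_foot_inside(self):
        d = point_segment_distance(np.array([[0.5, 2.0]]),
                                   np.array([[0.0, 0.0]]),
                                   np.array([[1.0, 0.0]]))
        assert d[0, 0] == pytest.approx(2.0)

    def test_clamped_to_endpoint(self):
        d = point_segment_distance(np.array([[-3.0, 4.0]]),
                                   np.array([[0.0, 0.0]]),
                                   np.array([[1.0, 0.0]]))
        assert d[0, 0] == pytest.approx(5.0)

    def test_degenerate_segment_is_point_distance(self):
        d = point_segment_distance(np.array([[3.0, 4.0]]),
                                   np.array([[0.0, 0.0]]),
                                   np.array([[0.0, 0.0]]))
        assert d[0, 0] == pytest.approx(5.0)


def brute_adtw(lab, pred):
    """Reference: minimum over all monotone maps, both directions."""
    lab = np.asarray(lab, float)
    pred = np.asarray(pred, float)
    cost = point_segment_distance(lab, pred[:-1], pred[1:])
    N, M = cost.shape
    best = np.inf
    for direction in (cost, cost[:, ::-1]):
        for alpha in itertools.combinations_with_replacement(range(M), N):
            val = sum(direction[i, a] for i, a in enumerate(alpha))
            best = min(best, val)
    return best / N


class TestADTW:
    def test_label_points_on_prediction_zero(self):
        pred = np.column_stack([np.linspace(0, 30, 20), np.zeros(20)])
        labels = np.array([[3.7, 0.0], [11.0, 0.0], [28.2, 0.0]])
        assert adtw(labels, pred) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_offset_oracle(self):
        pred = np.column_stack([np.linspace(0, 30, 20), np.zeros(20)])
        labels = np.array([[5.0, 2.0], [15.0, 2.0], [25.0, 2.0]])
        assert adtw(labels, pred) == pytest.approx(2.0)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(0)
        pred = np.cumsum(rng.normal(size=(15, 2)), axis=0)
        labels = pred[[2, 7, 12]] + rng.normal(scale=0.5, size=(3, 2))
        assert adtw(labels, pred) == pytest.approx(
            adtw(labels[::-1], pred), rel=1e-12)
        assert adtw(labels, pred) == pytest.approx(
            adtw(labels, pred[::-1]), rel=1e-12)

    def test_single_label_point(self):
        pred = np.array([[0.0, 0.0], [10.0, 0.0]])
        assert adtw(np.array([[5.0, 3.0]]), pred) == pytest.approx(3.0)

    def test_monotonicity_beats_independent_minimum_sometimes(self):
        # a label order inconsistent with the curve cannot do better than
        # the unconstrained per-point minimum
        pred = np.column_stack([np.linspace(0, 10, 11), np.zeros(11)])
        labels = np.array([[8.0, 1.0], [2.0, 1.0], [9.0, 1.0]])
        d = adtw(labels, pred)
        free = point_segment_distance(labels, pred[:-1], pred[1:]).min(axis=1)
        assert d >= free.mean() - 1e-12

    def test_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            n_lab = int(rng.integers(1, 5))
            n_pred = int(rng.integers(2, 7))
            pred = np.cumsum(rng.normal(size=(n_pred, 2)), axis=0)
            labels = rng.normal(scale=3.0, size=(n_lab, 2))
            assert adtw(labels, pred) == pytest.approx(
                brute_adtw(labels, pred), abs=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            adtw(np.zeros((0, 2)), np.zeros((5, 2)))
        with pytest.raises(ValueError):
            adtw(np.zeros((3, 2)), np.zeros((1, 2)))


class TestMatching:
    def straight(self, y, n=20):
        return np.column_stack([np.linspace(0, 30, n), np.full(n, float(y))])

    def test_obvious_pairing(self):
        labels = [self.straight(0)[[2, 10, 17]], self.straight(50)[[3, 9, 18]]]
        preds = [self.straight(50), self.straight(0)]
        pairs, deltas = match_labels_to_predictions(labels, preds)
        assert sorted(pairs) == [(0, 1), (1, 0)]
        assert max(deltas) < 1e-9

    def test_unmatched_when_too_far(self):
        labels = [self.straight(0)[[2, 10, 17]]]
        preds = [self.straight(500)]
        pairs, _ = match_labels_to_predictions(labels, preds, sigma_eps=3.0)
        assert pairs == []

    def test_no_double_assignment(self):
        labels = [self.straight(0)[[2, 10]], self.straight(1)[[3, 12]]]
        preds = [self.straight(0.5)]
        pairs, _ = match_labels_to_predictions(labels, preds)
        assert len(pairs) == 1

    def test_empty_inputs(self):
        assert match_labels_to_predictions([], []) == ([], [])


class TestTpFnRates:
    def test_perfect_detection(self):
        pairs = [(0, 0), (1, 1)]
        tp, fn = tp_fn_rates(pairs, [0.1, 0.2], n_labels=2, n_preds=2)
        assert tp == 1.0 and fn == 0.0

    def test_counts_with_threshold(self):
        # one good pair, one beyond σ_ε, one unmatched label, one extra pred
        pairs = [(0, 0), (1, 1)]
        tp, fn = tp_fn_rates(pairs, [1.0, 9.0], n_labels=3, n_preds=4,
                             sigma_eps=3.0)
        assert tp == pytest.approx(1 / 4)
        assert fn == pytest.approx(2 / 3)

    def test_empty_denominators_nan(self):
        tp, fn = tp_fn_rates([], [], n_labels=0, n_preds=0)
        assert np.isnan(tp) and np.isnan(fn)


class TestTrackingIntegrity:
    def test_consistent_track_is_one(self):
        assert tracking_integrity(["a"] * 17) == 1.0

    def test_two_half_blocks(self):
        assert tracking_integrity([1, 2]) == pytest.approx(0.5)
        assert tracking_integrity([1, 1, 2, 2]) == pytest.approx(0.5)

    def test_m_equal_blocks_gives_one_over_m(self):
        for m in (2, 3, 5):
            seq = sum(([i] * 4 for i in range(m)), [])
            assert tracking_integrity(seq) == pytest.approx(1 / m)

    def test_worked_example_three_blocks(self):
        # blocks of 3, 1, 2 over N=6: (9 + 1 + 4) / 36
        seq = ["a", "a", "a", "b", "c", "c"]
        assert tracking_integrity(seq) == pytest.approx(14 / 36)

    def test_single_frame_defect_scales_as_inverse_n(self):
        # one mislabeled frame: ι = ((N−1)² + 1)/N² → 1 − 2/N + O(N⁻²)
        for N in (10, 100, 1000):
            seq = [0] * (N - 1) + [1]
            expected = ((N - 1) ** 2 + 1) / N**2
            assert tracking_integrity(seq) == pytest.approx(expected)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            tracking_integrity([])


def _track_from(frames_cls, track_id):
    tr = Track(track_id=track_id)
    for f, cl in frames_cls:
        z = np.stack([cl, cl, cl])
        tr.add(f, Detection(z=z, score=1.0))
    return tr


class TestIntegrityOverDataset:
    def worm(self, t, speed=2.0, y=20.0, k=9):
        x = np.linspace(0, 16, k) + speed * t
        return np.column_stack([x, np.full(k, y)])

    def test_perfect_tracks_integrity_one(self):
        gt = {0: {t: self.worm(t) for t in range(10)}}
        tracks = [_track_from([(t, self.worm(t)) for t in range(10)], 7)]
        per_worm, mean, se = integrity_over_dataset(tracks, gt)
        assert per_worm[0] == 1.0 and mean == 1.0 and se == 0.0

    def test_identity_switch_halves_integrity(self):
        gt = {0: {t: self.worm(t) for t in range(10)}}
        tracks = [
            _track_from([(t, self.worm(t)) for t in range(5)], 1),
            _track_from([(t, self.worm(t)) for t in range(5, 10)], 2),
        ]
        per_worm, mean, _ = integrity_over_dataset(tracks, gt)
        assert per_worm[0] == pytest.approx(0.5)

    def test_missing_frames_count_against_integrity(self):
        gt = {0: {t: self.worm(t) for t in range(4)}}
        tracks = [_track_from([(t, self.worm(t)) for t in range(2)], 1)]
        per_worm, _, _ = integrity_over_dataset(tracks, gt)
        # identities: [1, 1, miss-a, miss-b] → (4 + 1 + 1)/16
        assert per_worm[0] == pytest.approx(6 / 16)

    def test_far_detection_not_matched(self):
        gt = {0: {t: self.worm(t) for t in range(4)}}
        tracks = [_track_from([(t, self.worm(t, y=90.0)) for t in range(4)],
                              1)]
        per_worm, _, _ = integrity_over_dataset(tracks, gt, sigma_eps=3.0)
        assert per_worm[0] == pytest.approx(4 / 16)

    def test_flip_invariant_matching(self):
        gt = {0: {t: self.worm(t) for t in range(6)}}
        tracks = [_track_from([(t, self.worm(t)[::-1]) for t in range(6)], 3)]
        per_worm, _, _ = integrity_over_dataset(tracks, gt)
        assert per_worm[0] == 1.0

    def test_mean_and_se_over_worms(self):
        gt = {0: {t: self.worm(t, y=20.0) for t in range(4)},
              1: {t: self.worm(t, y=60.0) for t in range(4)}}
        tracks = [
            _track_from([(t, self.worm(t, y=20.0)) for t in range(4)], 1),
            _track_from([(t, self.worm(t, y=60.0)) for t in range(2)], 2),
            _track_from([(t, self.worm(t, y=60.0)) for t in range(2, 4)], 3),
        ]
        per_worm, mean, se = integrity_over_dataset(tracks, gt)
        assert per_worm[0] == 1.0
        assert per_worm[1] == pytest.approx(0.5)
        assert mean == pytest.approx(0.75)
        assert se == pytest.approx(np.std([1.0, 0.5], ddof=1) / np.sqrt(2))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            EvalConfig(sigma_eps=0.0)
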