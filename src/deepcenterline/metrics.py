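"""Evaluation metrics: asymmetric DTW, TP/FN rates, tracking integrity.

Manual annotations are sparse (a handful of points along a worm), while
predictions are dense centerlines.  The asymmetric dynamic time warping
error assigns each label point to a prediction segment, monotonically along
the body in either direction, and averages the point-to-segment distances —
it is shift-invariant along the curve and robust to labellers skipping
low-visibility stretches.  Label-prediction pairing over a whole frame is a
rectangular assignment on these errors.  Track quality is summarized by the
tracking integrity ι: the probability that two uniformly chosen time points
of a ground-truth track carry the same predicted identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "EvalConfig", "adtw", "point_segment_distance",
    "match_labels_to_predictions", "tp_fn_rates", "tracking_integrity",
    "integrity_over_dataset",
]


@dataclass(frozen=True)
class EvalConfig:
    sigma_eps: float = 3.0  # px; label-prediction match cutoff

    def __post_init__(self):
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")


def point_segment_distance(points: np.ndarray, seg_a: np.ndarray,
                           seg_b: np.ndarray) -> np.ndarray:
    """Distances from N points to M segments [a_j, b_j]; returns (N, M).

    Uses the projection onto each segment clamped to its endpoints.
    """
    points = np.atleast_2d(points)
    ab = seg_b - seg_a                      # (M, 2)
    ap = points[:, None] - seg_a[None]      # (N, M, 2)
    denom = np.einsum("mj,mj->m", ab, ab)
    denom = np.where(denom > 0, denom, 1.0)
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / denom, 0.0, 1.0)
    closest = seg_a[None] + t[..., None] * ab[None]
    return np.linalg.norm(points[:, None] - closest, axis=-1)


def _monotone_dp(cost: np.ndarray) -> float:
    """min over non-decreasing maps α of Σ_i cost[i, α(i)] (O(NM))."""
    run = np.minimum.accumulate(cost[0])
    for i in range(1, cost.shape[0]):
        run = cost[i] + np.minimum.accumulate(run)
    return float(run.min())


def adtw(label_points, pred_centerline) -> float:
    """Asymmetric DTW error between sparse label points and a prediction.

    δ = min over monotonic (non-decreasing or non-increasing) assignments α
    of label points to prediction segments of (1/N) Σ d(i, α(i)), with d the
    point-to-segment Euclidean distance.  Both monotone directions are tried
    and the smaller mean returned.
    """
    lab = np.atleast_2d(np.asarray(label_points, dtype=float))
    pred = np.asarray(pred_centerline, dtype=float)
    if lab.size == 0 or pred.shape[0] < 2:
        raise ValueError("need ≥1 label point and ≥2 prediction points")
    cost = point_segment_distance(lab, pred[:-1], pred[1:])
    best = min(_monotone_dp(cost), _monotone_dp(cost[:, ::-1]))
    return best / lab.shape[0]


def match_labels_to_predictions(labels, preds, unmatched_cost: float | None = None,
                                sigma_eps: float = 3.0):
    """One-to-one partial assignment of labels to predictions by ADTW.

    Returns ``(pairs, deltas)`` where ``pairs`` is a list of
    (label_index, pred_index) and ``deltas`` the per-pair ADTW errors.
    Unmatched outcomes are priced at ``unmatched_cost`` (default 10 σ_ε, far
    above any acceptable match) through dummy padding, so no two predictions
    ever share a label.
    """
    if unmatched_cost is None:
        unmatched_cost = 10.0 * sigma_eps
    n, m = len(labels), len(preds)
    if n == 0 or m == 0:
        return [], []
    cost = np.empty((n, m))
    for i, lab in enumerate(labels):
        for j, pred in enumerate(preds):
            cost[i, j] = adtw(lab, pred)
    size = n + m
    full = np.full((size, size), 0.0)
    BIG = 1e9
    full[:n, :m] = cost
    full[:n, m:] = BIG
    full[n:, :m] = BIG
    np.fill_diagonal(full[:n, m:], unmatched_cost)
    np.fill_diagonal(full[n:, :m], unmatched_cost)
    rows, cols = linear_sum_assignment(full)
    pairs, deltas = [], []
    for r, c in zip(rows, cols):
        if r < n and c < m and full[r, c] < BIG:
            pairs.append((int(r), int(c)))
            deltas.append(float(cost[r, c]))
    return pairs, deltas


def tp_fn_rates(pairs, deltas, n_labels: int, n_preds: int,
                sigma_eps: float = 3.0):
    """TP and FN rates from an assignment with per-pair ADTW errors.

    TP rate: fraction of predictions assigned a label within σ_ε.
    FN rate: fraction of labels with no assigned prediction within σ_ε.
    Returns NaN for an empty denominator (undefined rate).
    """
    good = [(i, j) for (i, j), d in zip(pairs, deltas) if d <= sigma_eps]
    tp = len(good) / n_preds if n_preds else float("nan")
    fn = (n_labels - len(good)) / n_labels if n_labels else float("nan")
    return tp, fn


def tracking_integrity(identity_sequence) -> float:
    """ι = (1/N²) Σ_i Σ_j [I_i = I_j] for one ground-truth track.

    Equals 1 for a perfectly consistent track and 1/m for m equal-length
    identity blocks; interpretable as the probability that two uniformly
    random time points carry the same predicted identity.
    """
    ids = list(identity_sequence)
    if not ids:
        raise ValueError("empty identity sequence")
    N = len(ids)
    counts: dict = {}
    for i in ids:
        counts[i] = counts.get(i, 0) + 1
    return sum(c * c for c in counts.values()) / (N * N)


def integrity_over_dataset(tracks, ground_truth, sigma_eps: float = 3.0):
    """Per-worm integrity of predicted ``tracks`` against ground truth.

    ``ground_truth`` maps worm_id → {frame: (k, 2) centerline}.  For every
    ground-truth worm and frame, the predicted identity is the track whose
    detection at that frame has its central centerline closest (mean
    point distance after flip-minimization) within σ_ε·√k of the truth; a
    frame with no matching detection gets a unique "missing" identity so
    gaps count against integrity.  Returns (per-worm dict, mean, standard
    error).
    """
    # index detections by frame, with stacked centerlines for vectorization
    by_frame: dict[int, list] = {}
    for tr in tracks:
        for frame, det in tr.entries:
            by_frame.setdefault(frame, []).append((tr.track_id, det))
    stacked = {
        f: (np.array([tid for tid, _ in items]),
            np.array([det.z[1] for _, det in items]))
        for f, items in by_frame.items()
    }
    per_worm = {}
    missing_counter = [0]

    def identity_at(frame, truth_cl):
        if frame not in stacked:
            tids = cls = None
        else:
            tids, cls = stacked[frame]
        if tids is None or len(tids) == 0:
            missing_counter[0] += 1
            return f"missing-{missing_counter[0]}"
        k = truth_cl.shape[0]
        diff = cls - truth_cl
        diff_r = cls - truth_cl[::-1]
        d2 = np.minimum(np.einsum("mki,mki->m", diff, diff),
                        np.einsum("mki,mki->m", diff_r, diff_r))
        best = int(np.argmin(d2))
        if np.sqrt(d2[best] / k) > sigma_eps:  # RMS per-point distance
            missing_counter[0] += 1
            return f"missing-{missing_counter[0]}"
        return tids[best]

    for worm_id, frames in ground_truth.items():
        seq = [identity_at(f, np.asarray(cl)) for f, cl in sorted(frames.items())]
        per_worm[worm_id] = tracking_integrity(seq)
    vals = np.array(list(per_worm.values()))
    mean = float(vals.mean()) if vals.size else float("nan")
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return per_worm, mean, se
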