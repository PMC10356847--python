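"""Latent-space non-maximum suppression of candidate detections.

Instead of spatial overlap (IoU is ill-defined for overlapping slender
bodies), duplicates are declared through a learned latent embedding: two
candidates within a spatial cutoff σ_l are the same object with probability
``exp(−‖p_i − p_j‖²)``.  Greedy score-ordered acceptance with this
probability prunes the grid to one detection per organism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SuppressionConfig", "same_object_probability", "non_max_suppress"]


@dataclass(frozen=True)
class SuppressionConfig:
    tau_s: float = 0.5   # score threshold
    tau_o: float = 0.5   # same-object probability threshold
    sigma_l: float = 57.0  # spatial visibility cutoff (px)

    def __post_init__(self):
        if not (0 <= self.tau_s <= 1 and 0 <= self.tau_o <= 1):
            raise ValueError("thresholds must lie in [0, 1]")


def same_object_probability(det_i, det_j, sigma_l: float) -> float:
    """P(i↔j) = exp(−‖p_i − p_j‖²) if ‖x0_i − x0_j‖ ≤ σ_l, else 0."""
    if np.linalg.norm(det_i.x0 - det_j.x0) > sigma_l:
        return 0.0
    dp = det_i.latent - det_j.latent
    return float(np.exp(-float(dp @ dp)))


def non_max_suppress(candidates, config: SuppressionConfig | None = None):
    """Greedy latent-space NMS.

    Candidates below τ_s are dropped; the rest are visited in descending
    score order (ties broken by candidate index), each accepted candidate
    removing every remaining one whose same-object probability exceeds τ_o.
    Returns survivors in acceptance order.  Uses a uniform spatial hash of
    cell size σ_l so only pairs that can pass the spatial gate are examined.
    """
    if config is None:
        config = SuppressionConfig()
    cands = [c for c in candidates if c.score >= config.tau_s]
    if not cands:
        return []
    order = sorted(range(len(cands)),
                   key=lambda i: (-cands[i].score, i))
    # spatial hash on central centroids
    cell = max(config.sigma_l, 1e-9)
    buckets: dict[tuple, list] = {}
    for i, c in enumerate(cands):
        key = (int(np.floor(c.x0[0] / cell)), int(np.floor(c.x0[1] / cell)))
        buckets.setdefault(key, []).append(i)
    alive = np.ones(len(cands), dtype=bool)
    accepted = []
    for i in order:
        if not alive[i]:
            continue
        alive[i] = False
        accepted.append(cands[i])
        kx, ky = (int(np.floor(cands[i].x0[0] / cell)),
                  int(np.floor(cands[i].x0[1] / cell)))
        for dx_ in (-1, 0, 1):
            for dy_ in (-1, 0, 1):
                for j in buckets.get((kx + dx_, ky + dy_), ()):
                    if alive[j] and same_object_probability(
                            cands[i], cands[j], config.sigma_l) > config.tau_o:
                        alive[j] = False
    return accepted
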