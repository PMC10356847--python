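"""Identity-preserving linking of per-frame detections into tracks.

Because every detection carries past/present/future centerlines, linking
can use a *directed* metric rather than a symmetric distance: detection i at
time t matches detection j at t′ when i's present centerline agrees with
j's past one and i's future centerline agrees with j's present one.  Frame-
to-frame assignment is solved exactly as a rectangular linear sum assignment
with dummy rows/columns pricing track birth and death, after spatial gating
on centerline midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import flip_invariant_distance_sq

__all__ = ["LinkConfig", "Track", "directed_cost", "link_frames",
           "build_tracks"]


@dataclass(frozen=True)
class LinkConfig:
    spatial_cutoff: float = 38.0   # px, on central-centerline midpoints
    cost_max: float = 76.0         # price of non-assignment (birth/death)
    stride: int = 1                # frame stride; must equal triplet spacing
    min_track_length: int = 5      # stub-removal threshold (frames)
    max_gap: int = 2               # frames a track survives without a match

    def __post_init__(self):
        if self.spatial_cutoff <= 0:
            raise ValueError("spatial_cutoff must be positive")


@dataclass
class Track:
    track_id: int
    entries: list = field(default_factory=list)  # (frame_index, Detection)
    alive: bool = True

    def add(self, frame: int, det) -> None:
        self.entries.append((frame, det))

    @property
    def frames(self):
        return [f for f, _ in self.entries]

    def __len__(self):
        return len(self.entries)


def directed_cost(det_t, det_next) -> float:
    """d(x_i(t), x⁻_j(t′)) + d(x⁺_i(t), x_j(t′)) with flip-invariant d."""
    a = np.sqrt(flip_invariant_distance_sq(det_t.z[1], det_next.z[0]))
    b = np.sqrt(flip_invariant_distance_sq(det_t.z[2], det_next.z[1]))
    return float(a + b)


def link_frames(dets_t, dets_next, config: LinkConfig | None = None):
    """Minimum-cost one-to-one partial assignment between two frames.

    Returns a list of (i, j) index pairs.  Pairs whose central-centerline
    midpoints are farther than ``spatial_cutoff`` are excluded; leaving a
    detection unmatched costs ``cost_max``, implemented with dummy nodes so
    the rectangular assignment is solved exactly.
    """
    if config is None:
        config = LinkConfig()
    n, m = len(dets_t), len(dets_next)
    if n == 0 or m == 0:
        return []
    BIG = 1e9
    cost = np.full((n, m), BIG)
    mids_t = np.array([d.midpoint for d in dets_t])
    mids_n = np.array([d.midpoint for d in dets_next])
    gate = np.linalg.norm(mids_t[:, None] - mids_n[None], axis=-1) \
        <= config.spatial_cutoff
    gi, gj = np.nonzero(gate)
    if gi.size:
        # vectorized directed costs over the gated pairs only
        cur_mid = np.array([d.z[1] for d in dets_t])[gi]     # (P, k, 2)
        cur_fut = np.array([d.z[2] for d in dets_t])[gi]
        nxt_past = np.array([d.z[0] for d in dets_next])[gj]
        nxt_mid = np.array([d.z[1] for d in dets_next])[gj]

        def flip_min(a, b):
            dd = np.einsum("pki,pki->p", a - b, a - b)
            br = b[:, ::-1]
            dr = np.einsum("pki,pki->p", a - br, a - br)
            return np.minimum(dd, dr)

        cost[gi, gj] = (np.sqrt(flip_min(cur_mid, nxt_past))
                        + np.sqrt(flip_min(cur_fut, nxt_mid)))
    # dummy-augmented square problem: row i may match dummy column n+... at
    # cost_max (track death), column j may match dummy row (birth)
    size = n + m
    full = np.full((size, size), 0.0)
    full[:n, :m] = cost
    full[:n, m:] = BIG
    full[n:, :m] = BIG
    np.fill_diagonal(full[:n, m:], config.cost_max)
    np.fill_diagonal(full[n:, :m], config.cost_max)
    rows, cols = linear_sum_assignment(full)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols)
             if r < n and c < m and cost[r, c] < BIG]
    return pairs


def _align_to_reference(z: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Reverse all three centerlines when that brings the central one
    closer (plain Euclidean) to the reference central centerline."""
    direct = np.sum((z[1] - ref) ** 2)
    flipped = np.sum((z[1][::-1] - ref) ** 2)
    if flipped < direct:
        return z[:, ::-1]
    return z


def build_tracks(per_frame_detections, config: LinkConfig | None = None):
    """Sequentially link frames into tracks, then post-process.

    Unmatched detections open new tracks; an unmatched track stays linkable
    for up to ``max_gap`` further frames before it is closed, so isolated
    missed detections do not split identities.  Post-processing (i) reverses
    centerlines where needed so consecutive entries of a track keep a
    consistent point order, (ii) merges single-frame identity branches
    caused by duplicate detections (a one-entry track bridging the gap of a
    longer track whose neighbours match it), and (iii) deletes stub tracks
    shorter than ``min_track_length`` frames.
    """
    if config is None:
        config = LinkConfig()
    tracks: list[Track] = []
    active: list[Track] = []  # alive tracks, linkable within max_gap frames
    next_id = 0
    for frame, dets in enumerate(per_frame_detections):
        candidates = [tr for tr in active
                      if frame - tr.entries[-1][0] <= config.max_gap + 1]
        prev_dets = [tr.entries[-1][1] for tr in candidates]
        assignment = dict(link_frames(prev_dets, dets, config))
        matched_next = set(assignment.values())
        still_active = []
        for i, tr in enumerate(candidates):
            if i in assignment:
                tr.add(frame, dets[assignment[i]])
                still_active.append(tr)
            elif frame - tr.entries[-1][0] <= config.max_gap:
                still_active.append(tr)  # keep waiting within the gap
            else:
                tr.alive = False
        for j, det in enumerate(dets):
            if j not in matched_next:
                tr = Track(track_id=next_id)
                next_id += 1
                tr.add(frame, det)
                tracks.append(tr)
                still_active.append(tr)
        active = still_active
    _fix_branches(tracks, config)
    tracks = [t for t in tracks if len(t) >= config.min_track_length]
    for tr in tracks:
        _orient_track(tr)
    return tracks


def _orient_track(track: Track) -> None:
    """Head-consistency pass: align each entry's point order to the
    previous entry's central centerline."""
    for idx in range(1, len(track.entries)):
        frame, det = track.entries[idx]
        _, prev = track.entries[idx - 1]
        det.z = _align_to_reference(det.z, prev.z[1])


def _fix_branches(tracks, config: LinkConfig) -> None:
    """Merge short spurious branches back into their parent track.

    A duplicate detection can hijack a link for a few frames, splitting one
    identity into a long track, a short branch, and a continuation.  Any
    track shorter than ``min_track_length`` whose start abuts the end of a
    longer track (within the spatial cutoff) is appended to that track, so
    the continuation re-links by proximity of frames.
    """
    short = [t for t in tracks if len(t) < config.min_track_length]
    long_ = [t for t in tracks if len(t) >= config.min_track_length]
    for st in short:
        f0, d0 = st.entries[0]
        best = None
        best_cost = config.cost_max
        for lt in long_:
            fl, dl = lt.entries[-1]
            if fl == f0 - 1 and np.linalg.norm(
                    dl.midpoint - d0.midpoint) <= config.spatial_cutoff:
                c = directed_cost(dl, d0)
                if c < best_cost:
                    best, best_cost = lt, c
        if best is not None:
            for f, d in st.entries:
                best.add(f, d)
            st.entries.clear()
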