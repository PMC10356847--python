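"""Detection container and the CSV dialects used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Detection", "write_detections_csv", "read_detections_csv",
           "write_centerlines_csv", "read_centerlines_csv"]


@dataclass
class Detection:
    """One pruned or candidate detection.

    z : (3, k, 2) past/present/future centerlines.
    score : confidence in [0, 1].
    latent : (D,) latent vector used for duplicate suppression.
    x0 : (2,) centroid of the central centerline (px).
    frame : central frame index within the source video, if known.
    """

    z: np.ndarray
    score: float
    latent: np.ndarray = field(default=None)
    x0: np.ndarray = field(default=None)
    frame: int = -1

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.x0 is None:
            self.x0 = self.z[1].mean(axis=0)
        else:
            self.x0 = np.asarray(self.x0, dtype=float)
        if self.latent is not None:
            self.latent = np.asarray(self.latent, dtype=float)

    @property
    def midpoint(self) -> np.ndarray:
        """Midpoint of the central centerline (used for spatial gating)."""
        return self.z[1][self.z.shape[1] // 2]


def write_detections_csv(path, detections):
    """frame, det_id, score, x0x, x0y, p1..pD, then 3×k (x, y) columns."""
    rows = []
    for i, det in enumerate(detections):
        row = {"frame": det.frame, "det_id": i, "score": det.score,
               "x0x": det.x0[0], "x0y": det.x0[1]}
        if det.latent is not None:
            for d, v in enumerate(det.latent):
                row[f"p{d + 1}"] = v
        for t, tag in enumerate(("m", "c", "p")):
            for j, (x, y) in enumerate(det.z[t]):
                row[f"{tag}_x{j + 1}"] = x
                row[f"{tag}_y{j + 1}"] = y
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_detections_csv(path):
    df = pd.read_csv(path)
    latent_cols = sorted((c for c in df.columns if c.startswith("p")
                          and c[1:].isdigit()), key=lambda c: int(c[1:]))
    k = sum(c.startswith("c_x") for c in df.columns)
    out = []
    for _, row in df.iterrows():
        z = np.empty((3, k, 2))
        for t, tag in enumerate(("m", "c", "p")):
            for j in range(k):
                z[t, j] = (row[f"{tag}_x{j + 1}"], row[f"{tag}_y{j + 1}"])
        latent = np.array([row[c] for c in latent_cols]) if latent_cols else None
        out.append(Detection(z=z, score=float(row["score"]), latent=latent,
                             x0=np.array([row["x0x"], row["x0y"]]),
                             frame=int(row["frame"])))
    return out


def write_centerlines_csv(path, rows):
    """rows: iterable of (frame, id, score, (k, 2) points)."""
    out = []
    for frame, ident, score, pts in rows:
        row = {"frame": frame, "id": ident, "score": score}
        for j, (x, y) in enumerate(np.asarray(pts)):
            row[f"x{j + 1}"] = x
            row[f"y{j + 1}"] = y
        out.append(row)
    pd.DataFrame(out).to_csv(path, index=False)


def read_centerlines_csv(path):
    df = pd.read_csv(path)
    k = sum(c.startswith("x") and c[1:].isdigit() for c in df.columns)
    out = []
    for _, row in df.iterrows():
        pts = np.array([[row[f"x{j + 1}"], row[f"y{j + 1}"]]
                        for j in range(k)])
        out.append((int(row["frame"]), int(row["id"]), float(row["score"]),
                    pts))
    return out
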