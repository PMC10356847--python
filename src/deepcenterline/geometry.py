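"""Centerline representation, PCA shape compression, distances and scores.

A centerline is an ordered ``(k, 2)`` float array of equidistant points along
the skeleton of a slender body, in continuous pixel coordinates (x rightward,
y downward, origin at the frame's top-left corner; pixel centers sit at
half-integers).  Because head and tail cannot be told apart from a single
frame, all comparisons use a flip-invariant distance that takes the minimum
over the two possible point orderings.

Shapes are compressed with an eigenworm-style PCA basis fitted on
centroid-centered coordinates.  Reversing the point order of a centerline
acts linearly on the PCA components through an exchange-matrix conjugation,
which lets downstream code flip shapes directly in component space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "TripletWeights",
    "PCABasis",
    "resample_equidistant",
    "flip_invariant_distance_sq",
    "triplet_distance_sq",
    "fit_pca_basis",
    "encode",
    "decode",
    "flipped_components",
    "score_target",
    "align_triplet",
    "reversal_matrix",
]

DEFAULT_K = 49


@dataclass(frozen=True)
class TripletWeights:
    """Weights for past/present/future centerlines in the triplet distance.

    The central weight counts double: ``w = 2*w_minus = 2*w_plus``.  Weights
    are normalized to sum to one at construction.
    """

    w_minus: float = 0.25
    w: float = 0.5
    w_plus: float = 0.25

    def __post_init__(self):
        if min(self.w_minus, self.w, self.w_plus) < 0:
            raise ValueError("triplet weights must be nonnegative")
        total = self.w_minus + self.w + self.w_plus
        if total <= 0:
            raise ValueError("triplet weights must not all be zero")
        object.__setattr__(self, "w_minus", self.w_minus / total)
        object.__setattr__(self, "w", self.w / total)
        object.__setattr__(self, "w_plus", self.w_plus / total)

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.w_minus, self.w, self.w_plus])


def _as_points(x) -> np.ndarray:
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (k, 2) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("centerline contains non-finite coordinates")
    return pts


def resample_equidistant(polyline, k: int) -> np.ndarray:
    """Resample a polyline to ``k`` points at equal arc-length spacing.

    Endpoints are preserved exactly.  Raises ``ValueError`` on degenerate
    (zero total arc length) input.
    """
    pts = _as_points(polyline)
    if k < 2:
        raise ValueError("k must be at least 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        raise ValueError("degenerate polyline: zero arc length")
    target = np.linspace(0.0, total, k)
    x = np.interp(target, arclen, pts[:, 0])
    y = np.interp(target, arclen, pts[:, 1])
    out = np.column_stack([x, y])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def flip_invariant_distance_sq(x, x2) -> float:
    """Squared centerline distance, minimized over the two point orderings.

    ``d²(x, x') = min(Σ|x_i − x'_i|², Σ|x_i − x'_{k−i+1}|²)``.
    """
    a = _as_points(x)
    b = _as_points(x2)
    if a.shape != b.shape:
        raise ValueError(f"point count mismatch: {a.shape} vs {b.shape}")
    direct = np.sum((a - b) ** 2)
    reversed_ = np.sum((a - b[::-1]) ** 2)
    return float(min(direct, reversed_))


def triplet_distance_sq(z, z2, weights: TripletWeights | None = None) -> float:
    """Weighted triplet distance d_s² = Σ_t ω_t d²(z_t, z'_t)."""
    if weights is None:
        weights = TripletWeights()
    z = np.asarray(z, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z.shape != z2.shape or z.shape[0] != 3:
        raise ValueError(f"expected matching (3, k, 2) triplets, got {z.shape} vs {z2.shape}")
    w = weights.as_array
    return float(sum(w[t] * flip_invariant_distance_sq(z[t], z2[t]) for t in range(3)))


def reversal_matrix(k: int) -> np.ndarray:
    """Permutation on stacked (x…x, y…y) coordinates that reverses point order."""
    J = np.zeros((2 * k, 2 * k))
    idx = np.arange(k)
    J[idx, k - 1 - idx] = 1.0
    J[k + idx, 2 * k - 1 - idx] = 1.0
    return J


def _stack_coords(pts: np.ndarray) -> np.ndarray:
    # (k, 2) -> (2k,) with all x first, then all y
    return np.concatenate([pts[:, 0], pts[:, 1]])


def _unstack_coords(v: np.ndarray) -> np.ndarray:
    k = v.shape[-1] // 2
    return np.stack([v[..., :k], v[..., k:]], axis=-1)


@dataclass
class PCABasis:
    """Linear shape basis for centroid-centered centerlines.

    Attributes
    ----------
    mean : (2k,) mean of the centered stacked coordinates.
    A : (κ, 2k) orthonormal principal directions (components ← coordinates).
    flip_op : (κ, κ) component-space operator equivalent to reversing the
        point order; orthogonal involution when the ensemble was symmetrized.
    explained_variance : fraction of ensemble variance captured by the κ
        retained components.
    """

    mean: np.ndarray
    A: np.ndarray
    flip_op: np.ndarray
    explained_variance: float = 1.0
    component_std: np.ndarray = None  # per-component std over the ensemble

    @property
    def k(self) -> int:
        return self.mean.shape[0] // 2

    @property
    def kappa(self) -> int:
        return self.A.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mean", data=self.mean)
            f.create_dataset("A", data=self.A)
            f.create_dataset("flip_op", data=self.flip_op)
            if self.component_std is not None:
                f.create_dataset("component_std", data=self.component_std)
            f.attrs["k"] = self.k
            f.attrs["kappa"] = self.kappa
            f.attrs["explained_variance"] = self.explained_variance

    @classmethod
    def load(cls, path) -> "PCABasis":
        with h5py.File(path, "r") as f:
            return cls(
                mean=f["mean"][:],
                A=f["A"][:],
                flip_op=f["flip_op"][:],
                component_std=(f["component_std"][:]
                               if "component_std" in f else None),
                explained_variance=float(f.attrs["explained_variance"]),
            )


def fit_pca_basis(ensemble, kappa: int | None = None,
                  variance_target: float = 0.999) -> PCABasis:
    """Fit a PCA shape basis on an ensemble of centerlines.

    Each centerline is translated so its centroid is at the origin, stacked as
    a 2k-vector (x-block then y-block).  The ensemble is symmetrized by
    including each shape together with its point-order reversal, which makes
    the mean flip-symmetric and the retained subspace invariant under the
    reversal permutation — the component-space flip operator is then an exact
    orthogonal involution.

    If ``kappa`` is None, the smallest component count whose cumulative
    explained variance reaches ``variance_target`` is chosen.
    """
    shapes = [
        _stack_coords(_as_points(c) - np.mean(_as_points(c), axis=0))
        for c in ensemble
    ]
    if not shapes:
        raise ValueError("empty ensemble")
    X = np.asarray(shapes)
    k = X.shape[1] // 2
    J = reversal_matrix(k)
    X = np.concatenate([X, X @ J.T])  # symmetrize under point reversal
    if kappa is not None and X.shape[0] < kappa:
        raise ValueError("ensemble smaller than requested component count")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    frac = np.cumsum(var) / max(var.sum(), 1e-300)
    if kappa is None:
        kappa = int(np.searchsorted(frac, variance_target) + 1)
        kappa = min(kappa, Vt.shape[0])
    if kappa > Vt.shape[0]:
        raise ValueError("ensemble smaller than requested component count")
    A = Vt[:kappa]
    flip_op = A @ J @ A.T
    return PCABasis(
        mean=mean,
        A=A,
        flip_op=flip_op,
        explained_variance=float(frac[kappa - 1]),
        component_std=S[:kappa] / np.sqrt(X.shape[0]),
    )


def encode(x, basis: PCABasis):
    """Project a centerline onto the basis; returns (components λ, offset x0)."""
    pts = _as_points(x)
    if pts.shape[0] != basis.k:
        raise ValueError(f"centerline has {pts.shape[0]} points, basis expects {basis.k}")
    x0 = pts.mean(axis=0)
    lam = basis.A @ (_stack_coords(pts - x0) - basis.mean)
    return lam, x0


def decode(lam, x0, basis: PCABasis) -> np.ndarray:
    """Reconstruct a centerline from components λ and centroid offset x0."""
    lam = np.asarray(lam, dtype=float)
    v = basis.A.T @ lam + basis.mean
    return _unstack_coords(v) + np.asarray(x0, dtype=float)


def flipped_components(lam, basis: PCABasis) -> np.ndarray:
    """Component-space point-order reversal λ_f = flip_op · λ."""
    return basis.flip_op @ np.asarray(lam, dtype=float)


def score_target(z, z_label, sigma_s: float,
                 weights: TripletWeights | None = None) -> float:
    """Target confidence ŝ = exp(−d_s²/σ_s²) ∈ (0, 1]."""
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    return float(np.exp(-triplet_distance_sq(z, z_label, weights) / sigma_s**2))


def align_triplet(z) -> np.ndarray:
    """Reverse x⁻ and/or x⁺ when the reversed order is strictly closer
    (plain Euclidean) to the central centerline; ties keep the stored order."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 3 or z.shape[0] != 3:
        raise ValueError(f"expected (3, k, 2) triplet, got shape {z.shape}")
    out = z.copy()
    center = z[1]
    for t in (0, 2):
        direct = np.sum((z[t] - center) ** 2)
        flipped = np.sum((z[t][::-1] - center) ** 2)
        if flipped < direct:
            out[t] = z[t][::-1]
    return out
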