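"""Rendering of labeled synthetic microscopy clips and clip preprocessing.

Synthetic frames show bright worms (values near 1) on a dark background,
matching the zero-padded convolutions of the detector.  A worm is drawn by
stamping anti-aliased disks along its centerline with a tapered radius
profile; overlapping bodies combine by pixel-wise maximum.  Imaging
imperfections (uneven illumination, blur, sensor noise) are applied on top.

Real clips are brought onto the same intensity statistics by optional
polarity inversion, CLAHE, and affine moment matching, so a model trained
purely on synthetic data can be applied without retraining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import simulator
from .geometry import DEFAULT_K, resample_equidistant

__all__ = [
    "ArtefactConfig",
    "BatchConfig",
    "radius_profile",
    "render_frame",
    "add_artefacts",
    "normalize_percentile",
    "preprocess_real",
    "make_training_batch",
    "triplet_visibility",
]

STACK_SIZE = 11  # frames per detector input clip
PIXEL_SIZE_MM = 0.025  # mm per pixel; converts worm/mm² densities to counts


def radius_profile(s, R_tilde: float, a: float = 2.0, b: float = -1.0):
    """Local body radius r(s) = R̃ |sin(arccos(a·s + b))| for s ∈ [0, 1].

    With a=2, b=−1 the profile tapers symmetrically to zero at both ends and
    peaks at R̃ mid-body (equivalently R̃·√(1−(a·s+b)²)).
    """
    s = np.asarray(s, dtype=float)
    arg = a * s + b
    if np.any(np.abs(arg) > 1 + 1e-12):
        raise ValueError("a*s + b must stay within [-1, 1] on [0, 1]")
    arg = np.clip(arg, -1.0, 1.0)
    return R_tilde * np.abs(np.sin(np.arccos(arg)))


def _stamp_worm(image: np.ndarray, centerline: np.ndarray, radii: np.ndarray):
    """Draw one worm into ``image`` (max compositing) via dense disk stamping.

    Disk centers are spaced at most 0.5 px apart along the arc.  The
    anti-aliased coverage of a disk of radius r at pixel-center distance d is
    clip(r − d + 0.5, 0, 1); pixel centers sit at half-integer coordinates.
    """
    H, W = image.shape
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        return
    n = max(int(np.ceil(total / 0.5)) + 1, 2)
    t = np.linspace(0.0, total, n)
    cx = np.interp(t, arclen, centerline[:, 0])
    cy = np.interp(t, arclen, centerline[:, 1])
    s_par = np.linspace(0.0, 1.0, len(radii))
    r = np.interp(t / total, s_par, radii)

    rmax = r.max()
    x0 = max(int(np.floor(cx.min() - rmax - 1)), 0)
    x1 = min(int(np.ceil(cx.max() + rmax + 2)), W)
    y0 = max(int(np.floor(cy.min() - rmax - 1)), 0)
    y1 = min(int(np.ceil(cy.max() + rmax + 2)), H)
    if x0 >= x1 or y0 >= y1:
        return
    px = np.arange(x0, x1) + 0.5
    py = np.arange(y0, y1) + 0.5
    dx = px[None, None, :] - cx[:, None, None]
    dy = py[None, :, None] - cy[:, None, None]
    d = np.sqrt(dx**2 + dy**2)
    cov = np.clip(r[:, None, None] - d + 0.5, 0.0, 1.0).max(axis=0)
    np.maximum(image[y0:y1, x0:x1], cov, out=image[y0:y1, x0:x1])


def render_frame(centerlines, radii, H: int, W: int) -> np.ndarray:
    """Render worms as bright anti-aliased bodies on a dark background.

    ``centerlines`` is a sequence of (k, 2) arrays; ``radii`` either one
    radius-profile array shared by all worms or one per worm.  Overlaps take
    the pixel-wise maximum.
    """
    image = np.zeros((H, W))
    radii = np.asarray(radii, dtype=float)
    for i, cl in enumerate(centerlines):
        r = radii if radii.ndim == 1 else radii[i]
        _stamp_worm(image, np.asarray(cl, dtype=float), r)
    return image


@dataclass(frozen=True)
class ArtefactConfig:
    """Imaging-imperfection settings applied after rendering, in order:
    smooth background field, Gaussian blur, additive Gaussian noise."""

    background_amplitude: float = 0.12
    background_sigma_px: float = 48.0
    blur_sigma: float = 0.6
    noise_sigma: float = 0.03


def add_artefacts(image: np.ndarray, rng, config: ArtefactConfig | None = None
                  ) -> np.ndarray:
    """Apply uneven illumination, blur and sensor noise; clamp to [0, 1]."""
    if config is None:
        config = ArtefactConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    H, W = image.shape
    out = image.astype(float).copy()
    if config.background_amplitude > 0:
        field_ = rng.standard_normal((H, W))
        field_ = ndimage.gaussian_filter(field_, config.background_sigma_px,
                                         mode="reflect")
        span = field_.max() - field_.min()
        if span > 0:
            field_ = (field_ - field_.min()) / span
        out = out + config.background_amplitude * field_
    if config.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, config.blur_sigma)
    if config.noise_sigma > 0:
        out = out + config.noise_sigma * rng.standard_normal((H, W))
    return np.clip(out, 0.0, 1.0)


def normalize_percentile(clip: np.ndarray, lo: float = 1.0, hi: float = 99.0
                         ) -> np.ndarray:
    """Affine rescale mapping the lo/hi percentiles to 0/1, then clamp."""
    clip = np.asarray(clip, dtype=float)
    p_lo, p_hi = np.percentile(clip, [lo, hi])
    if p_hi <= p_lo:
        raise ValueError("clip is (nearly) constant; cannot normalize")
    return np.clip((clip - p_lo) / (p_hi - p_lo), 0.0, 1.0)


def preprocess_real(clip: np.ndarray, target_mean: float = 0.06,
                    target_std: float = 0.15, clahe_clip: float = 0.01,
                    clahe_tile: int = 64, auto_polarity: bool = True
                    ) -> np.ndarray:
    """Condition a real clip to resemble the synthetic training statistics.

    Steps: polarity inversion when the background is bright (median > 0.5),
    CLAHE per frame, then an affine intensity transform matching (mean, std)
    of the whole clip to the synthetic targets.
    """
    from skimage import exposure

    clip = np.asarray(clip, dtype=float)
    span = clip.max() - clip.min()
    if span > 0:
        clip = (clip - clip.min()) / span
    if auto_polarity and np.median(clip) > 0.5:
        clip = 1.0 - clip
    frames = np.stack([
        exposure.equalize_adapthist(f, kernel_size=clahe_tile,
                                    clip_limit=clahe_clip)
        for f in clip
    ])
    std = frames.std()
    if std > 0:
        frames = (frames - frames.mean()) / std * target_std + target_mean
    else:
        frames = frames - frames.mean() + target_mean
    return frames


def triplet_visibility(triplet: np.ndarray, H: int, W: int) -> bool:
    """A worm is visible iff all 3k triplet points lie inside the frame."""
    x = triplet[..., 0]
    y = triplet[..., 1]
    return bool(np.all((x >= 0) & (x < W) & (y >= 0) & (y < H)))


@dataclass(frozen=True)
class BatchConfig:
    """Study conditions for on-demand synthetic training data."""

    H: int = 64
    W: int = 64
    k: int = DEFAULT_K
    n_frames: int = STACK_SIZE
    fps: float = 20.0
    delta: int = 1           # frame spacing between x⁻, x, x⁺ targets
    n_worms_range: tuple = (0, 4)
    radius_range: tuple = (0.8, 1.3)
    radius_a: float = 2.0
    radius_b: float = -1.0
    # placement margin in mean worm lengths; negative keeps most centroids
    # inside the frame, so roughly two thirds of worms are fully visible
    # while the remainder exercises the border/partial-visibility cases
    margin_factor: float = -0.25
    artefacts: ArtefactConfig = field(default_factory=ArtefactConfig)
    sim_ranges: simulator.ParamRanges = field(
        default_factory=simulator.ParamRanges)


def _clip_from_trajectories(trajectories, radii_per_worm, config: BatchConfig,
                            rng) -> tuple:
    """Render one labeled clip from simulated trajectories."""
    T = config.n_frames
    frames = np.empty((T, config.H, config.W))
    for f in range(T):
        cls = [tr.centerlines[f] for tr in trajectories]
        img = render_frame(cls, radii_per_worm, config.H, config.W) \
            if cls else np.zeros((config.H, config.W))
        frames[f] = add_artefacts(img, rng, config.artefacts)
    mid = T // 2
    d = config.delta
    labels = {}
    visible = {}
    for worm_id, tr in enumerate(trajectories):
        z = np.stack([tr.centerlines[mid - d], tr.centerlines[mid],
                      tr.centerlines[mid + d]])
        labels[worm_id] = z
        visible[worm_id] = triplet_visibility(z, config.H, config.W)
    return frames, labels, visible


def make_training_batch(rng, batch: int, config: BatchConfig | None = None):
    """Generate ``batch`` labeled 11-frame clips with uniform worm counts.

    Returns ``(clips, labels, visibility)`` where ``clips`` is
    ``(batch, T, H, W)``, ``labels[i]`` maps worm_id → (3, k, 2) triplet and
    ``visibility[i]`` maps worm_id → bool (all 3k points inside the frame).
    Worm counts are uniform over ``config.n_worms_range`` inclusive, so the
    detector sees sparse and dense scenes with equal frequency.
    """
    if config is None:
        config = BatchConfig()
    if config.H % 16 or config.W % 16:
        raise ValueError("frame dimensions must be divisible by 16")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    duration = (config.n_frames - 1) / config.fps
    dt = 1.0 / config.fps
    lo, hi = config.n_worms_range
    clips = np.empty((batch, config.n_frames, config.H, config.W))
    labels = []
    visibility = []
    s_profile = np.linspace(0.0, 1.0, 2 * config.k)
    mean_L = 0.5 * (config.sim_ranges.L[0] + config.sim_ranges.L[1])
    margin = config.margin_factor * mean_L
    for b in range(batch):
        n_worms = int(rng.integers(lo, hi + 1))
        trajectories = simulator.simulate_population(
            n_worms, (config.H, config.W), duration, dt, rng, config.k,
            config.sim_ranges, margin=margin)
        radii = np.stack([
            radius_profile(s_profile, rng.uniform(*config.radius_range),
                           config.radius_a, config.radius_b)
            for _ in range(n_worms)
        ]) if n_worms else np.zeros((0, 2 * config.k))
        frames, lab, vis = _clip_from_trajectories(
            trajectories, radii, config, rng)
        clips[b] = normalize_percentile(frames) \
            if frames.max() > frames.min() else frames
        labels.append(lab)
        visibility.append(vis)
    return clips, labels, visibility


def augment_batch(clips, labels, rng):
    """Random flips, 90° rotations and time reversal, applied consistently
    to clips and labels (time reversal swaps the x⁻ and x⁺ label curves)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    clips = clips.copy()
    labels = [dict(l) for l in labels]
    B, T, H, W = clips.shape
    for b in range(B):
        if rng.random() < 0.5:  # horizontal flip
            clips[b] = clips[b, :, :, ::-1]
            labels[b] = {i: _flip_points(z, W, axis=0)
                         for i, z in labels[b].items()}
        if rng.random() < 0.5:  # vertical flip
            clips[b] = clips[b, :, ::-1, :]
            labels[b] = {i: _flip_points(z, H, axis=1)
                         for i, z in labels[b].items()}
        if H == W and rng.random() < 0.5:  # 90° rotation
            clips[b] = np.rot90(clips[b], axes=(1, 2))
            labels[b] = {i: _rot90_points(z, W) for i, z in labels[b].items()}
        if rng.random() < 0.5:  # time reversal
            clips[b] = clips[b, ::-1]
            labels[b] = {i: z[::-1].copy() for i, z in labels[b].items()}
    return clips, labels


def _flip_points(z, size, axis):
    z = z.copy()
    z[..., axis] = size - z[..., axis]
    return z


def _rot90_points(z, size):
    # np.rot90 maps pixel (row y, col x) -> (row size-1-x, col y)
    out = z.copy()
    out[..., 0] = z[..., 1]
    out[..., 1] = size - z[..., 0]
    return out
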