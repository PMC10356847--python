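"""Physics-based generation of swimming-nematode centerline trajectories.

The body posture is described by a tangent angle ψ(s, t) over the normalized
body coordinate s ∈ [0, 1], decomposed into a travelling sinusoidal wave and
a whole-body bend.  Integrating the unit tangent gives the centerline in a
body-aligned frame; rigid-body translation and rotation are then obtained
from resistive force theory (RFT): at zero Reynolds number the local drag
force is ``f = α_t (t̂·U) t̂ + α_n (n̂·U) n̂`` and the swimmer's velocity
``V`` and angular velocity ``Ω`` are fixed by requiring zero total force and
torque.  Drag anisotropy (α = α_n/α_t > 1) is what turns undulation into
propulsion; with isotropic drag a periodic stroke produces no net motion.

Worms are simulated independently — overlap between individuals is a visual
phenomenon handled by the renderer, not a mechanical interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import DEFAULT_K

__all__ = [
    "WormParams",
    "WormTrajectory",
    "ParamRanges",
    "sample_worm_params",
    "undulation_angle",
    "body_from_angles",
    "rft_rigid_velocities",
    "simulate",
    "simulate_population",
]


@dataclass(frozen=True)
class WormParams:
    """Parameters of one simulated worm.

    A : bend amplitude (rad); T : undulation period (s);
    k_u, k_s : spatial wavenumbers of the whole-body bend and the travelling
    wave (rad per unit body coordinate); rho1..rho3 : phases (rad);
    L : body length (px); gamma0 : initial orientation (rad);
    x_cm0 : initial center of mass (px); alpha_t : tangential drag
    coefficient; alpha_ratio : α = α_n/α_t (> 1 for propulsion).
    """

    A: float = 0.7
    T: float = 0.8
    k_u: float = 3.0
    k_s: float = 2 * np.pi
    rho1: float = 0.0
    rho2: float = 0.0
    rho3: float = 0.0
    L: float = 38.0
    gamma0: float = 0.0
    x_cm0: tuple = (0.0, 0.0)
    alpha_t: float = 1.0
    alpha_ratio: float = 1.8

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("period T must be positive")
        if self.L <= 0:
            raise ValueError("length L must be positive")
        if self.alpha_ratio <= 1:
            raise ValueError("drag anisotropy alpha_n/alpha_t must exceed 1")

    @property
    def alpha_n(self) -> float:
        return self.alpha_ratio * self.alpha_t


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling ranges for worm parameters.

    Defaults deliberately oversample behaviour relative to any single
    recording so the downstream detector sees a broad posture repertoire.
    """

    A: tuple = (0.3, 1.2)
    T: tuple = (0.4, 1.2)
    k_u: tuple = (0.0, 2 * np.pi)
    k_s: tuple = (2 * np.pi * 0.75, 2 * np.pi * 1.75)
    L: tuple = (30.0, 46.0)
    alpha_ratio: tuple = (1.2, 2.5)


@dataclass
class WormTrajectory:
    times: np.ndarray        # (T,)
    centerlines: np.ndarray  # (T, k, 2) lab-frame points
    gamma: np.ndarray        # (T,)
    x_cm: np.ndarray         # (T, 2)
    params: WormParams = None


def sample_worm_params(rng, ranges: ParamRanges | None = None,
                       frame_size: tuple | None = None) -> WormParams:
    """Draw one parameter set from the configured uniform ranges.

    ``rng`` is a ``numpy.random.Generator`` (pass ``np.random.default_rng(seed)``
    for reproducibility).  If ``frame_size=(H, W)`` is given, the initial
    center of mass is uniform over the frame.
    """
    if ranges is None:
        ranges = ParamRanges()
    u = rng.uniform
    if frame_size is not None:
        H, W = frame_size
        x_cm0 = (float(u(0, W)), float(u(0, H)))
    else:
        x_cm0 = (0.0, 0.0)
    return WormParams(
        A=float(u(*ranges.A)),
        T=float(u(*ranges.T)),
        k_u=float(u(*ranges.k_u)),
        k_s=float(u(*ranges.k_s)),
        rho1=float(u(0, 2 * np.pi)),
        rho2=float(u(0, 2 * np.pi)),
        rho3=float(u(0, 2 * np.pi)),
        L=float(u(*ranges.L)),
        gamma0=float(u(0, 2 * np.pi)),
        x_cm0=x_cm0,
        alpha_t=1.0,
        alpha_ratio=float(u(*ranges.alpha_ratio)),
    )


def undulation_angle(params: WormParams, s, t, amp_arg_scaled: bool = False):
    """Tangent angle ψ(s, t) = ψ_u + ψ_s of the undulation model.

    ψ_u = A cos(2πt/T + ρ1) cos(k_u s + ρ2) is the whole-body bend and
    ψ_s = Ã cos(2πt/T + k_s s + ρ3) the travelling wave, with the wave
    amplitude modulated as Ã = ½(1 + |sin(2πt)|) A.  ``amp_arg_scaled``
    switches the modulation argument to 2πt/T instead of 2πt.
    """
    s = np.asarray(s, dtype=float)
    p = params
    phase = 2 * np.pi * t / p.T
    psi_u = p.A * np.cos(phase + p.rho1) * np.cos(p.k_u * s + p.rho2)
    mod_arg = 2 * np.pi * (t / p.T if amp_arg_scaled else t)
    A_tilde = 0.5 * (1 + np.abs(np.sin(mod_arg))) * p.A
    psi_s = A_tilde * np.cos(phase + p.k_s * s + p.rho3)
    return psi_u + psi_s


def body_from_angles(psi, gamma: float, L: float, k: int = DEFAULT_K,
                     quad_factor: int = 8) -> np.ndarray:
    """Integrate the tangent angle into a centerline.

    x(s) = L ∫₀ˢ (cos(ψ+γ), sin(ψ+γ)) ds′, evaluated by trapezoidal
    quadrature on a fine grid (``quad_factor``·k nodes) and sampled at k
    points equidistant in s.  Arc length equals L up to quadrature error.
    """
    n = quad_factor * k
    s_fine = np.linspace(0.0, 1.0, n + 1)
    ang = np.asarray(psi(s_fine), dtype=float) + gamma
    tx = np.cos(ang)
    ty = np.sin(ang)
    ds = 1.0 / n
    # cumulative trapezoid from 0
    x = np.concatenate([[0.0], np.cumsum(0.5 * (tx[1:] + tx[:-1]) * ds)])
    y = np.concatenate([[0.0], np.cumsum(0.5 * (ty[1:] + ty[:-1]) * ds)])
    s_target = np.linspace(0.0, 1.0, k)
    return L * np.column_stack([np.interp(s_target, s_fine, x),
                                np.interp(s_target, s_fine, y)])


def rft_rigid_velocities(x: np.ndarray, shape_velocity: np.ndarray,
                         alpha_t: float, alpha_n: float):
    """Solve force- and torque-free RFT for rigid-body velocities.

    Given the centerline ``x`` (k, 2) and the deformation velocity field
    ``shape_velocity`` (k, 2), returns ``(V, Ω)`` such that the total drag
    force and torque of ``U = shape_velocity + V + Ω ẑ×(x − x_cm)`` vanish.
    The system is linear (3×3) and solved exactly.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(shape_velocity, dtype=float)
    k = x.shape[0]
    if k < 2:
        raise ValueError("need at least two centerline points")
    # tangents by central differences, normalized
    t_vec = np.gradient(x, axis=0)
    norms = np.linalg.norm(t_vec, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate centerline: zero-length tangent")
    t_hat = t_vec / norms
    n_hat = np.column_stack([-t_hat[:, 1], t_hat[:, 0]])
    # drag tensor D_i = α_t t̂t̂ᵀ + α_n n̂n̂ᵀ per point
    D = (alpha_t * np.einsum("ki,kj->kij", t_hat, t_hat)
         + alpha_n * np.einsum("ki,kj->kij", n_hat, n_hat))
    # uniform quadrature weights: equidistant-in-s samples of a uniform body,
    # so the center of mass is the plain centroid
    w = np.full(k, 1.0 / k)
    x_cm = x.mean(axis=0)
    r = x - x_cm
    r_perp = np.column_stack([-r[:, 1], r[:, 0]])  # ẑ × r

    def wrench(vel):
        """Total (Fx, Fy, τ) of drag forces for point velocity field ``vel``."""
        f = np.einsum("kij,kj->ki", D, vel)
        F = (w[:, None] * f).sum(axis=0)
        tau = (w * (r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0])).sum()
        return np.array([F[0], F[1], tau])

    ones = np.ones((k, 1))
    M = np.column_stack([
        wrench(ones * np.array([1.0, 0.0])),
        wrench(ones * np.array([0.0, 1.0])),
        wrench(r_perp),
    ])
    rhs = -wrench(u)
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular RFT system: {e}") from None
    V = sol[:2]
    Omega = float(sol[2])
    residual = wrench(u + V + Omega * r_perp)
    scale = max(np.abs(rhs).max(), 1.0)
    if np.abs(residual).max() > 1e-8 * scale:
        raise ValueError("RFT solve failed to reach force/torque balance")
    return V, Omega


def _body_frame_shape(params: WormParams, t: float, k: int,
                      amp_arg_scaled: bool = False) -> np.ndarray:
    """Centroid-centered body shape at orientation γ = 0."""
    body = body_from_angles(
        lambda s: undulation_angle(params, s, t, amp_arg_scaled), 0.0,
        params.L, k)
    return body - body.mean(axis=0)


def _body_frame_shapes(params: WormParams, times, k: int,
                       amp_arg_scaled: bool = False,
                       quad_factor: int = 8) -> np.ndarray:
    """Vectorized ``_body_frame_shape`` over many time points.

    Evaluates the tangent-angle field on a (time × arc-length) grid in one
    pass; per-element arithmetic and the sequential cumulative sums match
    the scalar path bitwise, so results equal per-time calls exactly.
    """
    n = quad_factor * k
    s_fine = np.linspace(0.0, 1.0, n + 1)
    t_arr = np.asarray(times, dtype=float)
    ang = undulation_angle(params, s_fine[None, :], t_arr[:, None],
                           amp_arg_scaled) + 0.0
    tx = np.cos(ang)
    ty = np.sin(ang)
    ds = 1.0 / n
    T = len(t_arr)
    X = np.concatenate(
        [np.zeros((T, 1)),
         np.cumsum(0.5 * (tx[:, 1:] + tx[:, :-1]) * ds, axis=1)], axis=1)
    Y = np.concatenate(
        [np.zeros((T, 1)),
         np.cumsum(0.5 * (ty[:, 1:] + ty[:, :-1]) * ds, axis=1)], axis=1)
    s_target = np.linspace(0.0, 1.0, k)
    out = np.empty((T, k, 2))
    for i in range(T):
        body = params.L * np.column_stack(
            [np.interp(s_target, s_fine, X[i]),
             np.interp(s_target, s_fine, Y[i])])
        out[i] = body - body.mean(axis=0)
    return out


def simulate(params: WormParams, duration: float, dt: float = 0.05,
             k: int = DEFAULT_K, substeps: int = 4,
             amp_arg_scaled: bool = False) -> WormTrajectory:
    """Integrate one worm's swimming trajectory.

    At every substep the body shape is built from ψ in a γ = 0 frame,
    the deformation velocity is estimated by central finite differences of
    consecutive body-frame shapes, RFT yields (V, Ω), and (x_cm, γ) advance
    by explicit Euler.  Frames are emitted every ``dt`` seconds; ``substeps``
    internal Euler steps per frame keep |Ω|·h small.
    """
    n_frames = int(round(duration / dt)) + 1
    h = dt / substeps
    # pass 1: collect every time at which a body-frame shape is needed,
    # replicating the integration loop's float arithmetic exactly, then
    # evaluate all shapes in one vectorized sweep (the dominant cost)
    times_needed = []
    t = 0.0
    for frame in range(n_frames):
        times_needed.append(t)  # frame emission
        if frame == n_frames - 1:
            break
        for _ in range(substeps):
            times_needed.append(t - 0.5 * h)
            times_needed.append(t + 0.5 * h)
            times_needed.append(t)
            t += h
        t = (frame + 1) * dt  # avoid drift from repeated addition
    shapes = _body_frame_shapes(params, times_needed, k, amp_arg_scaled)

    gamma = params.gamma0
    x_cm = np.array(params.x_cm0, dtype=float)
    times = np.empty(n_frames)
    centerlines = np.empty((n_frames, k, 2))
    gammas = np.empty(n_frames)
    x_cms = np.empty((n_frames, 2))

    idx = 0
    t = 0.0
    for frame in range(n_frames):
        times[frame] = t
        shape0 = shapes[idx]
        idx += 1
        c, s = np.cos(gamma), np.sin(gamma)
        R = np.array([[c, -s], [s, c]])
        centerlines[frame] = shape0 @ R.T + x_cm
        gammas[frame] = gamma
        x_cms[frame] = x_cm
        if frame == n_frames - 1:
            break
        for _ in range(substeps):
            shape_m = shapes[idx]
            shape_p = shapes[idx + 1]
            shape0 = shapes[idx + 2]
            idx += 3
            vel0 = (shape_p - shape_m) / h
            c, s = np.cos(gamma), np.sin(gamma)
            R = np.array([[c, -s], [s, c]])
            x_lab = shape0 @ R.T + x_cm
            vel_lab = vel0 @ R.T
            V, Omega = rft_rigid_velocities(
                x_lab, vel_lab, params.alpha_t, params.alpha_n)
            if abs(Omega) * h > 0.5:
                import warnings
                warnings.warn("large rotation per substep; decrease dt")
            x_cm = x_cm + h * V
            gamma = gamma + h * Omega
            t += h
        t = (frame + 1) * dt
    return WormTrajectory(times=times, centerlines=centerlines,
                          gamma=gammas, x_cm=x_cms, params=params)


def shape_ensemble(rng, n: int, k: int = DEFAULT_K,
                   ranges: ParamRanges | None = None) -> list:
    """Draw ``n`` posture snapshots from the undulation model.

    Each snapshot is a (k, 2) centerline at a random phase of a randomly
    parameterized worm, suitable for fitting the PCA shape basis.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    shapes = []
    for _ in range(n):
        p = sample_worm_params(rng, ranges)
        t = float(rng.uniform(0, 4 * p.T))
        shapes.append(body_from_angles(
            lambda s: undulation_angle(p, s, t), p.gamma0, p.L, k))
    return shapes


def simulate_population(n_worms: int, frame_size: tuple, duration: float,
                        dt: float = 0.05, rng=None, k: int = DEFAULT_K,
                        ranges: ParamRanges | None = None,
                        margin: float = 0.0) -> list:
    """Simulate ``n_worms`` independent worms with uniform initial positions.

    Overlaps are allowed by design — the worms do not interact mechanically.
    ``margin`` widens the placement region beyond the frame on every side so
    partially visible bodies occur at the borders.
    """
    if rng is None:
        rng = np.random.default_rng()
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    H, W = frame_size
    trajectories = []
    for _ in range(n_worms):
        params = sample_worm_params(rng, ranges)
        x_cm0 = (float(rng.uniform(-margin, W + margin)),
                 float(rng.uniform(-margin, H + margin)))
        params = replace(params, x_cm0=x_cm0)
        trajectories.append(simulate(params, duration, dt, k))
    return trajectories
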