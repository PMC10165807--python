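"""Seeded synthetic-data generators emulating optically patterned active-fluid
microscopy.

Every input the analysis pipeline consumes can be produced here: aligned
filamentous textures advected by programmed flows inside illumination
masks, photoswitching speed traces, bend-angle relaxation traces, and
confinement-dependent instability-threshold datasets. All generators are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .core import IlluminationSchedule, ImageSequence, RectRegion
from .stability import alpha_eff

__all__ = [
    "FlowSpec",
    "HydrodynamicParams",
    "gen_texture",
    "render_sequence",
    "gen_speed_trace",
    "gen_angle_trace",
    "gen_threshold_dataset",
]


@dataclass(frozen=True)
class FlowSpec:
    """Programmed in-plane flow applied inside the activation mask.

    kinds:
      uniform    — constant velocity ``(speed, 0)`` um/s
      extension  — affine normal strain-rate field, ``rate_xx``/``rate_yy`` 1/s
                   about the frame (or region) centre
      shear      — simple shear ``vx = speed * (y - y_c) / y_half``
      bend_mode  — transverse sinusoidal mode ``vy ∝ sin(k x)`` whose
                   amplitude grows so the mean absolute bend angle increases
                   at ``angle_rate`` rad/s
      turbulent  — frozen divergence-free random field (from a smoothed
                   random stream function) with RMS speed ``speed``
    """

    kind: str = "uniform"
    speed: float = 1.0
    correlation_length: float = 20.0
    wavevector: float = 0.05
    angle_rate: float = 0.002
    rate_xx: float = 0.0
    rate_yy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"uniform", "extension", "shear", "bend_mode", "turbulent"}:
            raise ValueError(f"unknown flow kind: {self.kind!r}")
        if self.speed < 0:
            raise ValueError("speed scale must be >= 0")


@dataclass(frozen=True)
class HydrodynamicParams:
    """Lumped hydrodynamic parameters of the confined active nematic.

    Only the combination alpha*(S0+xi)/(2*eta*DR*kappa) matters to the
    pipeline; individual members are generator bookkeeping, never fitted.
    """

    alpha: float = 1.0
    S0: float = 1.0
    xi: float = 1.0
    DR: float = 1.0
    kappa: float = 1.0
    eta: float = 1.0

    @property
    def alpha_eff_scale(self) -> float:
        return self.alpha * (self.S0 + self.xi) / (2 * self.eta * self.DR * self.kappa)


def gen_texture(
    seed: int,
    shape: tuple[int, int] = (256, 256),
    orientation: float = 0.0,
    correlation_length: float = 6.0,
    px_size: float = 1.0,
    speckle: float = 1.0,
) -> np.ndarray:
    """Anisotropic band-pass filtered random field mimicking an aligned
    microtubule network.

    Streaks run along ``orientation`` (rad, CCW from +x); the dominant
    structure-tensor direction of the output matches it to within ~2 deg.
    Intensities are scaled to [0, 1]. ``speckle`` sets the relative
    amplitude of an isotropic fine-grain component: bundle images carry
    intensity variation along the filaments, and a texture without it
    would make along-streak motion invisible to PIV (aperture problem).
    Use a small value (~0.2) to emulate a tightly shear-aligned network
    for orientation analyses.
    """
    if correlation_length < 2 * px_size:
        raise ValueError("correlation_length must be >= 2 * px_size")
    rng = np.random.default_rng(seed)
    # generate on an enlarged canvas so rotation never exposes padding
    pad = int(np.ceil(0.5 * max(shape) * (np.sqrt(2) - 1))) + 4
    big = (shape[0] + 2 * pad, shape[1] + 2 * pad)
    sig_across = max(correlation_length / px_size / 2.0, 1.0)
    sig_along = 10.0 * sig_across
    # elongated smoothing along x -> streaks along x; band-pass by
    # subtracting a coarser version to kill the DC pedestal. A fine
    # isotropic speckle component is blended in: bundle images carry
    # intensity variation along the filaments too, and without it the
    # along-streak displacement component is unobservable (aperture
    # problem) for the PIV stage.
    f = ndimage.gaussian_filter(rng.standard_normal(big), sigma=(sig_across, sig_along), mode="wrap")
    f -= ndimage.gaussian_filter(f, sigma=(4 * sig_across, 4 * sig_across), mode="wrap")
    f /= f.std()
    g = ndimage.gaussian_filter(rng.standard_normal(big), sigma=sig_across, mode="wrap")
    g -= ndimage.gaussian_filter(g, sigma=(4 * sig_across, 4 * sig_across), mode="wrap")
    g /= g.std()
    f = f + speckle * g
    deg = np.degrees(orientation)
    if abs(deg) > 1e-12:
        # image rows run downward, so a CCW physical rotation is CW in
        # array index space
        f = ndimage.rotate(f, -deg, reshape=False, order=3, mode="wrap")
    f = f[pad : pad + shape[0], pad : pad + shape[1]]
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo)


def _velocity_field(
    flow: FlowSpec, shape: tuple[int, int], px_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (vx, vy) in um/s for the steady part of the flow."""
    ny, nx = shape
    y = np.arange(ny)[:, None] * px_size
    x = np.arange(nx)[None, :] * px_size
    zeros = np.zeros(shape)
    if flow.kind == "uniform":
        return np.full(shape, flow.speed), zeros
    if flow.kind == "extension":
        xc, yc = (nx - 1) * px_size / 2.0, (ny - 1) * px_size / 2.0
        return flow.rate_xx * (x - xc) + zeros, flow.rate_yy * (y - yc) + zeros
    if flow.kind == "shear":
        yc = (ny - 1) * px_size / 2.0
        y_half = max(yc, px_size)
        return flow.speed * (y - yc) / y_half + zeros, zeros
    if flow.kind == "bend_mode":
        # small-time velocity of the triangle-wave bend (see
        # _bend_displacement); exact amplitudes are handled there
        k = flow.wavevector
        return zeros, flow.angle_rate / k * np.arcsin(np.sin(k * x)) * k + zeros
    # turbulent: derivative of a smoothed random stream function
    rng = np.random.default_rng(flow.seed)
    psi = rng.standard_normal(shape)
    sig = max(flow.correlation_length / px_size, 1.0)
    psi = ndimage.gaussian_filter(psi, sig, mode="wrap")
    vx = np.gradient(psi, px_size, axis=0)
    vy = -np.gradient(psi, px_size, axis=1)
    rms = np.sqrt(np.mean(vx**2 + vy**2))
    if rms > 0:
        vx *= flow.speed / rms
        vy *= flow.speed / rms
    return vx, vy


def _bend_displacement(
    flow: FlowSpec, shape: tuple[int, int], px_size: float, t_on: float
) -> np.ndarray:
    """Transverse displacement of the growing bend mode at activated age
    ``t_on``.

    A triangle-wave profile (period 2*pi/wavevector) with uniform slope
    magnitude tan(angle_rate * t_on) is used so the local filament tilt
    |atan(du_y/dx)| equals angle_rate * t_on everywhere except at the
    fold lines, making the mean deviation angle grow linearly at exactly
    the programmed rate (a sinusoidal profile would compress the mean
    through the atan at large amplitudes).
    """
    ny, nx = shape
    x = np.arange(nx)[None, :] * px_size
    k = flow.wavevector
    tri = np.arcsin(np.sin(k * x)) / k  # slope is +-1
    return np.broadcast_to(np.tan(flow.angle_rate * t_on) * tri, shape).copy()


def render_sequence(
    texture: np.ndarray,
    flow: FlowSpec,
    schedule: IlluminationSchedule,
    n_frames: int,
    dt: float,
    px_size: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImageSequence:
    """Warp ``texture`` by the time-integrated flow, gated by the schedule.

    Advection acts only inside the active episode's region (full frame if
    the episode has no region) and only while the light is on; elsewhere
    and during dark intervals frames are static up to additive Gaussian
    camera noise. Backward-mapping bilinear warping is used, so intensity
    is conserved under pure translation up to boundary effects.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    texture = np.asarray(texture, dtype=float)
    ny, nx = texture.shape
    vx, vy = _velocity_field(flow, texture.shape, px_size)

    mask = np.ones(texture.shape, dtype=bool)
    region = None
    for ep in schedule.episodes:
        if ep.intensity > 0 and ep.region is not None:
            region = ep.region
    if region is not None:
        rs, cs = region.pixel_slices(px_size, texture.shape)
        mask[:] = False
        mask[rs, cs] = True

    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)
    frames = np.empty((n_frames, ny, nx))
    for k in range(n_frames):
        t = k * dt
        t_on = schedule.on_seconds(t)
        if t_on == 0:
            warped = texture
        else:
            if flow.kind == "bend_mode":
                ux = np.zeros_like(texture)
                uy = _bend_displacement(flow, texture.shape, px_size, t_on)
            elif flow.kind == "extension":
                # constant-strain-rate stretching moves material points
                # exponentially; the backward displacement at a fixed pixel
                # is (x - xc)(1 - exp(-rate t)), which keeps the Eulerian
                # strain increment per frame exactly rate * dt
                y = np.arange(ny)[:, None] * px_size
                x = np.arange(nx)[None, :] * px_size
                xc, yc = (nx - 1) * px_size / 2.0, (ny - 1) * px_size / 2.0
                ux = (x - xc) * (1.0 - np.exp(-flow.rate_xx * t_on)) + np.zeros_like(texture)
                uy = (y - yc) * (1.0 - np.exp(-flow.rate_yy * t_on)) + np.zeros_like(texture)
            else:
                ux, uy = vx * t_on, vy * t_on
            ux = np.where(mask, ux, 0.0) / px_size
            uy = np.where(mask, uy, 0.0) / px_size
            if np.abs(ux).max() == 0 and np.abs(uy).max() == 0:
                warped = texture
            else:
                warped = ndimage.map_coordinates(
                    texture, [rows - uy, cols - ux], order=3, mode="reflect"
                )
        if noise_sd > 0:
            warped = warped + rng.normal(0.0, noise_sd, texture.shape)
        frames[k] = warped
    return ImageSequence(frames, px_size_um=px_size, dt_s=dt)


def _episode_segments(
    schedule: IlluminationSchedule, t_total: float
) -> list[tuple[str, float, float]]:
    """Alternating (state, t0, t1) segments covering [0, t_total]."""
    segs: list[tuple[str, float, float]] = []
    t = 0.0
    for ep in schedule.episodes:
        if ep.t_start > t:
            segs.append(("off", t, min(ep.t_start, t_total)))
        state = "on" if ep.intensity > 0 else "off"
        segs.append((state, ep.t_start, min(ep.t_end, t_total)))
        t = ep.t_end
        if t >= t_total:
            break
    if t < t_total:
        segs.append(("off", t, t_total))
    return [(s, a, b) for s, a, b in segs if b > a]


def gen_speed_trace(
    vmax: float,
    tau_on: float,
    tau_off: float,
    schedule: IlluminationSchedule,
    dark_speed: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 2.0,
    t_total: float | None = None,
    dark_creep: float = 0.0,
) -> "SpeedTrace":
    """Mean-speed trace obeying the photoswitching kinetics.

    Within each on-episode the noiseless mean rises as
    ``dark + (vmax - dark) * (1 - exp(-t'/tau_on))``; after each
    deactivation it decays as a normalized logistic
    ``2 / (1 + exp(t'/tau_off))`` from the speed at deactivation toward
    the dark baseline. ``dark_creep`` (um/s per s) adds an optional linear
    drift of the dark baseline, emulating sample ageing; off by default.
    """
    from .flowfield import SpeedTrace  # deferred: avoid import cycle

    if not (vmax > dark_speed >= 0):
        raise ValueError("need vmax > dark_speed >= 0")
    if tau_on <= 0 or tau_off <= 0:
        raise ValueError("time constants must be positive")
    if t_total is None:
        t_total = schedule.t_end
    times = np.arange(0.0, t_total + dt / 2, dt)
    segs = _episode_segments(schedule, t_total)

    v = np.empty_like(times)
    level = dark_speed  # speed entering the current segment
    for state, a, b in segs:
        sel = (times >= a) & (times <= b if (state, a, b) == segs[-1] else times < b)
        tt = times[sel] - a
        dark_t = dark_speed + dark_creep * times[sel]
        if state == "on":
            v[sel] = dark_t + (vmax - dark_t) * (1.0 - np.exp(-tt / tau_on))
            level = dark_speed + dark_creep * b + (vmax - dark_speed) * (
                1.0 - np.exp(-(b - a) / tau_on)
            )
        else:
            amp = max(level - dark_speed, 0.0)
            v[sel] = dark_t + amp * 2.0 / (1.0 + np.exp(tt / tau_off))
            level = dark_speed + dark_creep * b + amp * 2.0 / (
                1.0 + np.exp((b - a) / tau_off)
            )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, v.shape)
    intensity = np.asarray(schedule.intensity_at(times))
    return SpeedTrace(times=times, speed=v, intensity=intensity)


def gen_angle_trace(
    gamma_dot: float,
    tau: float,
    r: float,
    C: float,
    schedule: IlluminationSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 2.0,
    t_total: float | None = None,
) -> "AngleTrace":
    """Mean bend-angle trace: linear activated growth, two-timescale decay.

    During on-episodes <theta> grows linearly at ``gamma_dot``; after each
    deactivation it follows ``exp(-t'/tau)*gamma_dot*t' + C'*exp(-t'/r)``
    with t' from the deactivation and C' the angle at deactivation. For an
    initial dark segment C' is the ``C`` argument, so a schedule that is a
    single dark interval yields exactly the relaxation model from t = 0.
    """
    from .orientation import AngleTrace  # deferred: avoid import cycle

    if gamma_dot < 0:
        raise ValueError("gamma_dot must be >= 0")
    if tau <= 0 or r <= 0:
        raise ValueError("time constants must be positive")
    if t_total is None:
        t_total = schedule.t_end
    times = np.arange(0.0, t_total + dt / 2, dt)
    segs = _episode_segments(schedule, t_total)

    theta = np.empty_like(times)
    level = C  # angle entering the current segment
    for state, a, b in segs:
        sel = (times >= a) & (times <= b if (state, a, b) == segs[-1] else times < b)
        tt = times[sel] - a
        if state == "on":
            theta[sel] = level + gamma_dot * tt
            level = level + gamma_dot * (b - a)
        else:
            theta[sel] = np.exp(-tt / tau) * gamma_dot * tt + level * np.exp(-tt / r)
            span = b - a
            level = np.exp(-span / tau) * gamma_dot * span + level * np.exp(-span / r)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sd, theta.shape)
    intensity = np.asarray(schedule.intensity_at(times))
    return AngleTrace(times=times, angle=theta, intensity=intensity)


def gen_threshold_dataset(
    a: float,
    geometries: Sequence[tuple[float, float, float]],
    rel_noise: float = 0.0,
    seed: int = 0,
    n_rep: int = 1,
) -> "pd.DataFrame":
    """Instability-threshold dataset ``I* = a * alpha_eff(L, W, H) * (1 + eps)``.

    ``geometries`` are (L, W, H) in um; ``rel_noise`` is the standard
    deviation of the multiplicative Gaussian perturbation. Returns a
    DataFrame with columns L_um, W_um, H_um, I_threshold, se, n.
    """
    import pandas as pd

    if a <= 0:
        raise ValueError("activity coefficient a must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for L, W, H in geometries:
        if min(L, W, H) <= 0:
            raise ValueError("all dimensions must be positive")
        base = a * alpha_eff(L, W, H)
        vals = base * (1.0 + rng.normal(0.0, rel_noise, n_rep)) if rel_noise > 0 else np.full(n_rep, base)
        rows.append(
            {
                "L_um": L,
                "W_um": W,
                "H_um": H,
                "I_threshold": float(np.mean(vals)),
                "se": float(np.std(vals, ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else 0.0,
                "n": n_rep,
            }
        )
    return pd.DataFrame(rows)
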