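"""Accumulated displacement, region strain traces, and regime classification.

PIV velocity fields are integrated on their fixed (Eulerian) grid into a
cumulative displacement series; region-averaged normal strains
gamma_xx = <d u_x / d x> and gamma_yy = <d u_y / d y> then distinguish
the quiescent (no motion), sliding (extension along the alignment only)
and buckling (transverse growth) responses of a photoactivated region,
and locate the instability-threshold intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ImageSequence, RectRegion
from .flowfield import VelocityField

__all__ = [
    "DisplacementSeries",
    "StrainTrace",
    "NOT_REACHED",
    "accumulate_displacement",
    "strain_trace",
    "region_intensity_trace",
    "classify_regime",
    "threshold_intensity",
]

#: Sentinel returned when no tested intensity crosses the buckling threshold.
NOT_REACHED = None


@dataclass
class DisplacementSeries:
    """Cumulative displacement on a fixed PIV grid.

    ``ux``/``uy`` have shape (T, ny, nx) in um with the first snapshot
    identically zero; ``ever_invalid`` marks nodes whose increment was
    missing (treated as zero) at any step.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    times: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    ever_invalid: np.ndarray


@dataclass
class StrainTrace:
    """Region-averaged cumulative normal strains over time."""

    times: np.ndarray
    gamma_xx: np.ndarray
    gamma_yy: np.ndarray
    region: RectRegion | None = None

    @property
    def delta_gamma_yy(self) -> float:
        return float(self.gamma_yy[-1] - self.gamma_yy[0])

    @property
    def final_gamma_xx(self) -> float:
        return float(self.gamma_xx[-1])


def accumulate_displacement(fields: Sequence[VelocityField], dt: float) -> DisplacementSeries:
    """Eulerian accumulation u(t_k) = sum_{j<k} v_j * dt at fixed nodes.

    With n velocity fields the series has n+1 snapshots, the first zero.
    Invalid nodes contribute a zero increment and are flagged.
    """
    if len(fields) < 2:
        raise ValueError("need at least 2 velocity fields")
    f0 = fields[0]
    for f in fields[1:]:
        if not f0.same_grid(f):
            raise ValueError("velocity fields are on different grids")
    ny, nx = f0.vx.shape
    T = len(fields) + 1
    ux = np.zeros((T, ny, nx))
    uy = np.zeros((T, ny, nx))
    ever_invalid = np.zeros((ny, nx), dtype=bool)
    for k, f in enumerate(fields):
        inc_x = np.where(f.valid, f.vx, 0.0) * dt
        inc_y = np.where(f.valid, f.vy, 0.0) * dt
        ever_invalid |= ~f.valid
        ux[k + 1] = ux[k] + inc_x
        uy[k + 1] = uy[k] + inc_y
    t0 = fields[0].t_s
    times = t0 + dt * np.arange(T)
    return DisplacementSeries(x_um=f0.x_um, y_um=f0.y_um, times=times,
                              ux=ux, uy=uy, ever_invalid=ever_invalid)


def strain_trace(disp: DisplacementSeries, region: RectRegion, erode: int = 1) -> StrainTrace:
    """Region-averaged gamma_xx(t), gamma_yy(t) by central differences.

    Displacement gradients are taken on the PIV grid; the averaging
    region is eroded by ``erode`` grid nodes from the rectangle boundary
    so windows straddling the activation edge are excluded.
    """
    X, Y = np.meshgrid(disp.x_um, disp.y_um)
    inside = region.contains(X, Y)
    if erode > 0:
        from scipy import ndimage
        inside = ndimage.binary_erosion(inside, iterations=erode)
    if np.sum(np.any(inside, axis=0)) < 3 or np.sum(np.any(inside, axis=1)) < 3:
        raise ValueError("region covers fewer than 3x3 grid nodes after erosion")
    gxx = np.empty(len(disp.times))
    gyy = np.empty(len(disp.times))
    for k in range(len(disp.times)):
        duxdx = np.gradient(disp.ux[k], disp.x_um, axis=1)
        duydy = np.gradient(disp.uy[k], disp.y_um, axis=0)
        gxx[k] = np.mean(duxdx[inside])
        gyy[k] = np.mean(duydy[inside])
    return StrainTrace(times=disp.times, gamma_xx=gxx, gamma_yy=gyy, region=region)


def region_intensity_trace(seq: ImageSequence, region: RectRegion) -> np.ndarray:
    """Mean fluorescence inside the region per frame, normalized to the
    first frame; a proxy for material flux through the region boundary."""
    rs, cs = region.pixel_slices(seq.px_size_um, seq.shape)
    vals = seq.frames[:, rs, cs].mean(axis=(1, 2))
    if vals[0] == 0:
        raise ValueError("first-frame region intensity is zero; cannot normalize")
    return vals / vals[0]


def classify_regime(strain: StrainTrace, eps_x: float = 0.005, eps_y: float = 0.005) -> str:
    """Label the response of an activated region.

    buckling if the net transverse strain growth exceeds ``eps_y``
    (transverse motion is the bend-instability signature, so it takes
    precedence); else sliding if the final extension gamma_xx exceeds
    ``eps_x``; else quiescent.
    """
    if strain.delta_gamma_yy > eps_y:
        return "buckling"
    if strain.final_gamma_xx > eps_x:
        return "sliding"
    return "quiescent"


def threshold_intensity(
    results: Sequence[tuple[float, float]], eps_y: float = 0.005
):
    """Smallest tested intensity whose transverse strain growth exceeds
    the buckling threshold.

    ``results`` are (intensity, delta_gamma_yy over the activation
    window) pairs sorted by intensity. Returns ``NOT_REACHED`` (None)
    when no intensity qualifies.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 tested intensities")
    intens = [I for I, _ in results]
    if any(b < a for a, b in zip(intens, intens[1:])):
        raise ValueError("results must be sorted by intensity")
    for I, dgyy in results:
        if dgyy > eps_y:
            return float(I)
    return NOT_REACHED
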