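"""Photoswitching kinetics of opto-kinesin driven flows.

Cycle segmentation from the illumination schedule, the bounded-exponential
activation fit v(t) = vmax (1 - exp(-t/tau_on)), the logistic deactivation
fit v_hat(t) = 2 / (1 + exp(t/tau_off)) on normalized decays, per-cycle
plateau/dark summaries, and the intensity-speed response with its
saturation point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import IlluminationSchedule
from .flowfield import SpeedTrace

__all__ = [
    "OnFit",
    "OffFit",
    "CycleSummary",
    "IntensityResponse",
    "FitError",
    "segment_cycles",
    "fit_activation",
    "fit_deactivation",
    "normalized_deactivation_segment",
    "cycle_summaries",
    "intensity_response",
]


class FitError(RuntimeError):
    """A kinetics fit failed to converge or the data violate the model."""


@dataclass(frozen=True)
class OnFit:
    """Activation fit: v(t) = vmax (1 - exp(-t / tau_on))."""

    vmax: float
    tau_on: float
    vmax_se: float
    tau_on_se: float
    residual_norm: float
    degenerate: bool = False


@dataclass(frozen=True)
class OffFit:
    """Deactivation fit: v_hat(t) = 2 / (1 + exp(t / tau_off))."""

    tau_off: float
    tau_off_se: float
    residual_norm: float


@dataclass(frozen=True)
class CycleSummary:
    cycle: int
    t_start: float
    plateau_speed: float
    dark_speed: float


@dataclass
class IntensityResponse:
    """Mean speed per tested illumination intensity and its saturation."""

    intensity: np.ndarray
    mean_speed: np.ndarray
    se: np.ndarray
    n: np.ndarray
    saturation_intensity: float


def segment_cycles(
    schedule: IlluminationSchedule, span: tuple[float, float] | None = None
) -> list[tuple[str, float, float]]:
    """Alternating ('on'|'off', t_start, t_end) intervals covering the span.

    Segmentation uses only the schedule, never the measured trace. The
    span defaults to [first episode start, last episode end]; a wider span
    adds leading/trailing dark intervals.
    """
    if not schedule.episodes:
        raise ValueError("empty schedule")
    t0, t1 = span if span is not None else (schedule.t_start, schedule.t_end)
    segs: list[tuple[str, float, float]] = []
    t = t0
    for ep in schedule.episodes:
        if ep.t_end <= t0 or ep.t_start >= t1:
            continue
        if ep.t_start > t:
            segs.append(("off", t, ep.t_start))
        label = "on" if ep.intensity > 0 else "off"
        a, b = max(ep.t_start, t0), min(ep.t_end, t1)
        if segs and segs[-1][0] == label:
            segs[-1] = (label, segs[-1][1], b)
        else:
            segs.append((label, a, b))
        t = b
    if t < t1:
        if segs and segs[-1][0] == "off":
            segs[-1] = ("off", segs[-1][1], t1)
        else:
            segs.append(("off", t, t1))
    return segs


def _on_model(t, vmax, tau):
    return vmax * (1.0 - np.exp(-t / tau))


def fit_activation(trace: SpeedTrace, fix_vmax: float | None = None) -> OnFit:
    """Fit the bounded-exponential rise to one on-interval of a speed trace.

    Times are re-zeroed to the interval start. By default vmax and tau_on
    are fitted jointly, initialized at max(v) and (time to half max)/ln 2;
    pass ``fix_vmax`` to fit tau_on alone with the plateau pinned.
    """
    t = trace.times - trace.times[0]
    v = trace.speed
    if len(t) < 5:
        raise ValueError("need at least 5 points for the activation fit")
    slope = stats.linregress(t, v).slope
    if slope < 0 and v[0] > v[-1]:
        raise FitError("trace is decreasing; not an activation transient")
    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        raise FitError("non-positive speeds; cannot fit activation")
    # time to half-max as a tau seed
    above = np.nonzero(v >= 0.5 * vmax0)[0]
    t_half = t[above[0]] if len(above) else t[-1]
    tau0 = max(t_half / np.log(2.0), (t[1] - t[0]) / 10.0)
    if np.ptp(v) < 1e-12 * max(vmax0, 1.0):
        # constant trace: instantaneous rise, tau -> 0 bound
        return OnFit(vmax=vmax0, tau_on=0.0, vmax_se=0.0, tau_on_se=np.nan,
                     residual_norm=0.0, degenerate=True)
    try:
        if fix_vmax is None:
            popt, pcov = optimize.curve_fit(
                _on_model, t, v, p0=[vmax0, tau0],
                bounds=([0, 0], [np.inf, np.inf]), maxfev=10000,
            )
            vmax, tau = popt
            perr = np.sqrt(np.diag(pcov))
            vmax_se, tau_se = perr
        else:
            popt, pcov = optimize.curve_fit(
                lambda tt, tau: _on_model(tt, fix_vmax, tau), t, v,
                p0=[tau0], bounds=(0, np.inf), maxfev=10000,
            )
            vmax, tau = fix_vmax, popt[0]
            vmax_se, tau_se = 0.0, float(np.sqrt(pcov[0, 0]))
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"activation fit did not converge: {exc}") from exc
    resid = v - _on_model(t, vmax, tau)
    return OnFit(vmax=float(vmax), tau_on=float(tau), vmax_se=float(vmax_se),
                 tau_on_se=float(tau_se), residual_norm=float(np.linalg.norm(resid)))


def _off_model(t, tau):
    return 2.0 / (1.0 + np.exp(t / tau))


def normalized_deactivation_segment(
    trace: SpeedTrace, schedule: IlluminationSchedule, off_index: int = 0, n_norm: int = 3
) -> SpeedTrace:
    """Extract the ``off_index``-th dark interval that follows an on
    interval and normalize it by the mean of the last ``n_norm`` on-state
    points before the transition."""
    segs = segment_cycles(schedule, span=(trace.times[0], trace.times[-1] + 1e-9))
    pairs = [
        (segs[i], segs[i + 1])
        for i in range(len(segs) - 1)
        if segs[i][0] == "on" and segs[i + 1][0] == "off"
    ]
    if off_index >= len(pairs):
        raise ValueError("no such deactivation transition in the schedule")
    (_, on0, on1), (_, off0, off1) = pairs[off_index]
    on_sel = (trace.times >= on0) & (trace.times < on1)
    v_ref = float(np.mean(trace.speed[on_sel][-n_norm:]))
    if v_ref <= 0:
        raise FitError("non-positive pre-deactivation speed; cannot normalize")
    seg = trace.restrict(off0, off1)
    return SpeedTrace(seg.times, seg.speed / v_ref, seg.intensity)


def fit_deactivation(trace: SpeedTrace) -> OffFit:
    """Fit the normalized logistic decay to one off-interval.

    ``trace`` must already be normalized so that its value at the
    deactivation instant is 1 (see ``normalized_deactivation_segment``);
    times are re-zeroed to the interval start.
    """
    t = trace.times - trace.times[0]
    v = trace.speed
    if len(t) < 5:
        raise ValueError("need at least 5 points for the deactivation fit")
    if stats.linregress(t, v).slope > 0 and v[-1] > v[0]:
        raise FitError("trace is rising; not a deactivation transient")
    # half-value 2/(1+e^(t/tau)) = 1/2 at t = tau ln 3
    below = np.nonzero(v <= 0.5)[0]
    tau0 = max((t[below[0]] if len(below) else t[-1]) / np.log(3.0), (t[1] - t[0]) / 10.0)
    try:
        popt, pcov = optimize.curve_fit(
            _off_model, t, v, p0=[tau0], bounds=(0, np.inf), maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"deactivation fit did not converge: {exc}") from exc
    tau = float(popt[0])
    resid = v - _off_model(t, tau)
    return OffFit(tau_off=tau, tau_off_se=float(np.sqrt(pcov[0, 0])),
                  residual_norm=float(np.linalg.norm(resid)))


def cycle_summaries(
    trace: SpeedTrace, schedule: IlluminationSchedule
) -> tuple[list[CycleSummary], float | None]:
    """Per-cycle plateau and dark speeds plus the dark-speed trend.

    Plateau = median speed over the last half of each on interval; dark =
    median over the last half of each off interval that follows it.
    The trend slope (um/s per s) comes from an ordinary linear regression
    of dark speeds on cycle start times; None (undefined) for one cycle.
    """
    segs = segment_cycles(schedule, span=(trace.times[0], trace.times[-1] + 1e-9))
    summaries: list[CycleSummary] = []
    k = 0

    def _median_last_half(a: float, b: float) -> float:
        mid = (a + b) / 2.0
        sel = (trace.times >= mid) & (trace.times < b)
        if not np.any(sel):
            sel = (trace.times >= a) & (trace.times < b)
        return float(np.median(trace.speed[sel])) if np.any(sel) else np.nan

    for i, (label, a, b) in enumerate(segs):
        if label != "on":
            continue
        plateau = _median_last_half(a, b)
        dark = np.nan
        for lbl2, a2, b2 in segs[i + 1 :]:
            if lbl2 == "off":
                dark = _median_last_half(a2, b2)
                break
        summaries.append(CycleSummary(cycle=k, t_start=a, plateau_speed=plateau, dark_speed=dark))
        k += 1
    if not summaries:
        raise ValueError("schedule contains no on intervals")
    with_dark = [s for s in summaries if np.isfinite(s.dark_speed)]
    slope: float | None = None
    if len(with_dark) >= 2:
        slope = float(stats.linregress(
            [s.t_start for s in with_dark], [s.dark_speed for s in with_dark]
        ).slope)
    return summaries, slope


def intensity_response(
    records: list[tuple[float, float]], saturation_fraction: float = 0.95
) -> IntensityResponse:
    """Mean +/- s.e. speed per intensity and the saturation intensity.

    ``records`` are (intensity, speed) pairs, e.g. plateau speeds from
    cycle summaries at different illumination levels. The saturation
    intensity is the smallest tested intensity whose mean speed reaches
    ``saturation_fraction`` of the sweep maximum.
    """
    by_I: dict[float, list[float]] = {}
    for I, v in records:
        by_I.setdefault(float(I), []).append(float(v))
    if len(by_I) < 3:
        raise ValueError("need at least 3 distinct intensities")
    intensity = np.array(sorted(by_I))
    means = np.array([np.mean(by_I[I]) for I in intensity])
    ns = np.array([len(by_I[I]) for I in intensity])
    ses = np.array([
        np.std(by_I[I], ddof=1) / np.sqrt(len(by_I[I])) if len(by_I[I]) > 1 else 0.0
        for I in intensity
    ])
    vmax = means.max()
    sat_idx = np.nonzero(means >= saturation_fraction * vmax)[0][0]
    return IntensityResponse(
        intensity=intensity, mean_speed=means, se=ses, n=ns,
        saturation_intensity=float(intensity[sat_idx]),
    )
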