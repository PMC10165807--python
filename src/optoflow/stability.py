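"""Confined active-nematic instability threshold.

A uniformly aligned extensile fluid confined to an activated box of
length L (along alignment), width W and height H goes unstable to bend
only when its effective activity exceeds a geometry-dependent bound:

    alpha_eff(L, W, H) = pi^2 L^2 (1/L^2 + 1/W^2 + 1/H^2)^2   if 1/L^2 > 1/W^2 + 1/H^2
                       = 4 pi^2 (1/W^2 + 1/H^2)               otherwise

The two branches coincide at 1/L^2 = 1/W^2 + 1/H^2, so the bound is
continuous and saturates (becomes L-independent) for long regions.
Assuming active stress proportional to illumination intensity,
I = a * alpha_eff, the single coefficient ``a`` maps threshold-intensity
measurements onto the geometric bound.

Note the right-hand side above carries units of um^-2; ``a`` is reported
as intensity per alpha_eff-unit in whatever intensity unit the dataset
uses, and any display-unit conversion is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StabilityFit",
    "GenericScalingFit",
    "alpha_eff",
    "fit_activity_coefficient",
    "predict_threshold",
    "fit_generic_scaling",
]


@dataclass(frozen=True)
class StabilityFit:
    """Origin-constrained slope of I_threshold versus alpha_eff."""

    a: float
    se: float
    residual_norm: float
    n: int

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("activity coefficient must be positive")


@dataclass(frozen=True)
class GenericScalingFit:
    """Phenomenological comparison fit I = gA / L^2 + gC."""

    gA: float
    gC: float
    residual_norm: float


def alpha_eff(L, W, H):
    """Geometric instability bound (um^-2) for an activated L x W x H box.

    Vectorized over numpy inputs; raises on non-positive dimensions.
    """
    L = np.asarray(L, dtype=float)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(L <= 0) or np.any(W <= 0) or np.any(H <= 0):
        raise ValueError("all dimensions must be positive")
    invL2 = 1.0 / L**2
    invWH2 = 1.0 / W**2 + 1.0 / H**2
    short = np.pi**2 * L**2 * (invL2 + invWH2) ** 2
    long_ = 4.0 * np.pi**2 * invWH2
    out = np.where(invL2 > invWH2, short, long_)
    return float(out) if out.ndim == 0 else out


def fit_activity_coefficient(data: pd.DataFrame) -> StabilityFit:
    """Fit I_threshold = a * alpha_eff(L, W, H) by least squares through
    the origin, inverse-variance weighted when standard errors are given.

    ``data`` needs columns L_um, W_um, H_um, I_threshold and optionally
    se (per-point standard error of the threshold intensity).
    """
    if len(data) < 2:
        raise ValueError("need at least 2 records")
    x = alpha_eff(data["L_um"].to_numpy(), data["W_um"].to_numpy(), data["H_um"].to_numpy())
    y = data["I_threshold"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all records share one alpha_eff; slope unidentifiable")
    w = np.ones_like(y)
    if "se" in data.columns:
        se = data["se"].to_numpy(dtype=float)
        if np.all(se > 0):
            w = 1.0 / se**2
    a = float(np.sum(w * x * y) / np.sum(w * x * x))
    resid = y - a * x
    dof = max(len(y) - 1, 1)
    # standard error of the origin-constrained weighted slope
    s2 = float(np.sum(w * resid**2) / dof)
    se_a = float(np.sqrt(s2 / np.sum(w * x * x)))
    return StabilityFit(a=a, se=se_a, residual_norm=float(np.linalg.norm(np.sqrt(w) * resid)), n=len(y))


def predict_threshold(L, W, H, fit: StabilityFit):
    """Predicted threshold intensity a * alpha_eff(L, W, H).

    Constant in L once the region is long enough that
    1/L^2 < 1/W^2 + 1/H^2 (saturated branch).
    """
    return fit.a * alpha_eff(L, W, H)


def fit_generic_scaling(data: pd.DataFrame) -> GenericScalingFit:
    """Least-squares fit of the phenomenological form I = gA / L^2 + gC."""
    L = data["L_um"].to_numpy(dtype=float)
    y = data["I_threshold"].to_numpy(dtype=float)
    if len(np.unique(L)) < 2:
        raise ValueError("need at least 2 distinct L values")
    X = np.column_stack([1.0 / L**2, np.ones_like(L)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return GenericScalingFit(gA=float(coef[0]), gC=float(coef[1]), residual_norm=float(np.linalg.norm(resid)))
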