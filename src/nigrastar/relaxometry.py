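"""Voxel-wise R2* estimation from multi-echo magnitude volumes.

Two readings of "linear least-squares fit to a mono-exponential function
with free baseline" are provided:

``loglinear``
    Ordinary / weighted least squares of ln S on TE with a free
    intercept (the baseline is the free multiplicative S0).  The slope
    is -R2*.  By default each echo is weighted by its squared signal,
    the standard first-order variance stabilisation for log-transformed
    magnitude data (log noise variance ~ sigma^2 / S^2).

``nonlinear_offset``
    Three-parameter fit S(TE) = S0 exp(-R2* TE) + C with an additive
    baseline C, solved by Levenberg-style least squares initialised from
    the log-linear fit.  Reduces to the log-linear solution when C = 0
    and the data are noise-free.

Voxels with any non-positive echo (log undefined) are marked unfittable
and excluded from the output mask rather than clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .phantom import EchoTrain, MultiEchoVolume, VolumeMap

__all__ = [
    "FitResult",
    "R2StarMap",
    "fit_voxel_loglinear",
    "fit_voxel_nonlinear_offset",
    "make_mask",
    "fit_map",
]

SENTINEL = np.nan  # value carried by voxels outside the fitted mask


@dataclass
class FitResult:
    r2star: float  # s^-1
    s0: float
    baseline: float = 0.0
    r_squared: float = np.nan
    method: Literal["loglinear", "nonlinear_offset"] = "loglinear"
    valid: bool = True
    converged: bool = True


@dataclass
class R2StarMap:
    """3D R2* map (s^-1) with per-voxel fit quality and fitted-voxel mask."""

    values: np.ndarray
    quality: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    method: str = "loglinear"
    qc: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def _loglinear_core(signals: np.ndarray, te_s: np.ndarray, weighted: bool):
    """Weighted least squares of ln S on TE for a batch of voxels.

    ``signals`` is (n_voxels, n_echoes), all entries > 0.  Returns
    (r2star, s0, r_squared) arrays.  Weights w_i = S_i^2 when
    ``weighted``; unit weights otherwise.  Used by both the scalar and
    the map-level fit so they are bit-identical.
    """
    y = np.log(signals)
    w = signals**2 if weighted else np.ones_like(signals)
    sw = w.sum(axis=1)
    xbar = (w * te_s).sum(axis=1) / sw
    ybar = (w * y).sum(axis=1) / sw
    dx = te_s[None, :] - xbar[:, None]
    dy = y - ybar[:, None]
    sxx = (w * dx * dx).sum(axis=1)
    sxy = (w * dx * dy).sum(axis=1)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = dy - slope[:, None] * dx
    sst = (w * dy * dy).sum(axis=1)
    ssr = (w * resid * resid).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / sst, 1.0)
    r2 = np.clip(r2, 0.0, 1.0)
    return -slope, np.exp(intercept), r2


def fit_voxel_loglinear(
    signal: np.ndarray, echoes: EchoTrain, weighted: bool = True
) -> FitResult:
    """Log-linear mono-exponential fit for one voxel.

    Any non-positive intensity makes the voxel unfittable (``valid``
    False); the slope of ln S on TE (seconds) gives R2* in s^-1.
    """
    s = np.asarray(signal, dtype=float)
    if s.ndim != 1 or s.size != echoes.n_echoes:
        raise ValueError("signal length must match the echo train")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        return FitResult(np.nan, np.nan, 0.0, np.nan, "loglinear", valid=False)
    r2star, s0, rsq = _loglinear_core(s[None, :], echoes.echo_times_s, weighted)
    return FitResult(float(r2star[0]), float(s0[0]), 0.0, float(rsq[0]),
                     "loglinear")


def fit_voxel_nonlinear_offset(
    signal: np.ndarray,
    echoes: EchoTrain,
    init: FitResult | None = None,
) -> FitResult:
    """Three-parameter fit S(TE) = S0 exp(-R2* TE) + C.

    Initialised from the log-linear fit (baseline 0) unless ``init`` is
    given.  Needs >= 4 echoes (3 parameters + 1 dof).  Non-convergence
    or degenerate input flags the voxel and falls back to the init.
    """
    s = np.asarray(signal, dtype=float)
    if echoes.n_echoes < 4:
        raise ValueError("offset model needs at least 4 echoes")
    if s.ndim != 1 or s.size != echoes.n_echoes:
        raise ValueError("signal length must match the echo train")
    if not np.all(np.isfinite(s)) or np.all(s <= 0):
        return FitResult(np.nan, np.nan, np.nan, np.nan, "nonlinear_offset",
                         valid=False, converged=False)
    te = echoes.echo_times_s
    if init is None or not init.valid:
        init = fit_voxel_loglinear(s, echoes)
    if init.valid:
        p0 = np.array([init.s0, max(init.r2star, 0.0), 0.0])
    else:
        p0 = np.array([float(s.max()), 1.0, 0.0])

    def resid(p):
        s0, r2, c = p
        return s0 * np.exp(-r2 * te) + c - s

    sol = least_squares(resid, p0, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=2000)
    s0, r2star, c = sol.x
    sst = float(((s - s.mean()) ** 2).sum())
    ssr = float((sol.fun**2).sum())
    rsq = 1.0 if sst == 0 else max(0.0, min(1.0, 1.0 - ssr / sst))
    ok = bool(sol.success) and s0 > 0
    if not ok:
        return FitResult(init.r2star, init.s0, 0.0, init.r_squared,
                         "nonlinear_offset", valid=init.valid, converged=False)
    return FitResult(float(r2star), float(s0), float(c), rsq,
                     "nonlinear_offset")


def make_mask(volume: MultiEchoVolume, threshold_fraction: float = 0.1) -> np.ndarray:
    """Object mask from the first echo.

    A voxel is kept iff its first-echo intensity exceeds
    ``threshold_fraction`` times a robust maximum (the 99th percentile
    of the first echo).  An empty mask warns but does not raise.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    first = volume.data[..., 0]
    robust_max = np.percentile(first, 99)
    mask = first > threshold_fraction * robust_max
    if not mask.any():
        warnings.warn("make_mask produced an empty mask", stacklevel=2)
    return mask


def fit_map(
    volume: MultiEchoVolume,
    mask: np.ndarray | None = None,
    method: Literal["loglinear", "nonlinear_offset"] = "loglinear",
    weighted: bool = True,
) -> R2StarMap:
    """Fit every masked voxel; unmasked/unfittable voxels carry NaN.

    The log-linear path is vectorised through the same kernel as the
    per-voxel fit, so results are bit-identical.  The QC dict counts
    fitted, excluded (non-positive echo), and non-converged voxels.
    """
    if method not in ("loglinear", "nonlinear_offset"):
        raise ValueError(f"unknown fit method {method!r}")
    shape = volume.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask and volume must share a grid")
    values = np.full(shape, SENTINEL)
    quality = np.full(shape, SENTINEL)
    fitted = np.zeros(shape, dtype=bool)
    sig = volume.data[mask]  # (n, n_echoes), lexicographic voxel order
    fittable = np.all(sig > 0, axis=1) & np.all(np.isfinite(sig), axis=1)
    n_nonconv = 0
    if method == "loglinear":
        r2star = np.full(sig.shape[0], np.nan)
        rsq = np.full(sig.shape[0], np.nan)
        if fittable.any():
            r2, _, q = _loglinear_core(sig[fittable], volume.echo_train.echo_times_s,
                                       weighted)
            r2star[fittable] = r2
            rsq[fittable] = q
    else:
        r2star = np.full(sig.shape[0], np.nan)
        rsq = np.full(sig.shape[0], np.nan)
        for i in np.flatnonzero(fittable):
            fr = fit_voxel_nonlinear_offset(sig[i], volume.echo_train)
            if not fr.converged:
                n_nonconv += 1
            if fr.valid:
                r2star[i] = fr.r2star
                rsq[i] = fr.r_squared
            else:
                fittable[i] = False
    values[mask] = r2star
    quality[mask] = rsq
    ok = np.zeros(sig.shape[0], dtype=bool)
    ok[:] = fittable
    fitted[mask] = ok
    qc = {
        "method": method,
        "weighted": bool(weighted) if method == "loglinear" else None,
        "mask_voxels": int(mask.sum()),
        "fitted_voxels": int(fitted.sum()),
        "excluded_nonpositive": int(mask.sum() - fittable.sum() - n_nonconv),
        "nonconverged": n_nonconv,
    }
    return R2StarMap(values, quality, fitted, volume.voxel_size, method, qc)
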