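"""Variable-flip-angle T1 mapping and the observed-T1 correction for qMT.

The three-point SPGR (FLASH) series is inverted with the standard linearized
DESPOT1 transform: plotting ``y = S/sin(a)`` against ``x = S/tan(a)`` turns
the spoiled gradient-echo equation into a straight line with slope
``E1 = exp(-TR/T1)`` and intercept ``M0 (1 - E1)``.

In a two-pool tissue the longitudinal recovery measured by such a series is
the slowest-decaying eigenmode of the coupled relaxation-exchange system,
not the intrinsic free-pool T1.  :func:`derive_t1f` inverts that relation:
given the observed T1 and the exchange parameters it returns the free-pool
T1 whose 2x2 exchange-relaxation matrix has its slowest eigenvalue at
``-1/t1_observed``; :func:`observed_t1_from_two_pool` is the forward map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "T1Map",
    "fit_vfa_t1",
    "derive_t1f",
    "observed_t1_from_two_pool",
]


@dataclass
class T1Map:
    """Voxel-wise VFA T1 fit results on a masked grid.

    ``valid`` is False wherever the linearized fit was degenerate (slope
    outside (0, 1), non-positive signals) or the voxel lies outside the mask.
    """

    t1: np.ndarray
    m0: np.ndarray
    r2_fit: np.ndarray
    valid: np.ndarray
    mask: np.ndarray


def fit_vfa_t1(
    signals: np.ndarray,
    flips_deg: np.ndarray,
    tr_ms: float,
    nonlinear: bool = False,
):
    """Invert the SPGR signal equation for (T1, M0) from a VFA series.

    Parameters
    ----------
    signals : array, shape (..., n_flips)
        Measured SPGR magnitudes; leading dimensions are voxels.
    flips_deg : array, shape (n_flips,)
        Excitation flip angles in degrees (>= 2 distinct values).
    tr_ms : float
        Repetition time in milliseconds (common to all volumes).
    nonlinear : bool
        If True, polish the linearized solution with a bounded
        nonlinear least-squares refinement per voxel (slower).

    Returns
    -------
    t1 : array, seconds (NaN where invalid)
    m0 : array, signal units (NaN where invalid)
    valid : boolean array
        False for degenerate voxels (slope <= 0 or >= 1, bad signals);
        no exception is raised for those.
    """
    signals = np.asarray(signals, dtype=float)
    flips = np.radians(np.asarray(flips_deg, dtype=float))
    if flips.ndim != 1 or len(np.unique(flips)) < 2:
        raise ValueError("need at least two distinct flip angles")
    if signals.shape[-1] != flips.size:
        raise ValueError("signals last axis must match number of flip angles")
    tr_s = tr_ms * 1e-3
    if tr_s <= 0:
        raise ValueError("tr must be positive")

    y = signals / np.sin(flips)
    x = signals / np.tan(flips)
    n = flips.size
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=-1)
    sxy = np.sum((x - xm) * (y - ym), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym[..., 0] - slope * xm[..., 0]
        valid = (
            np.isfinite(slope)
            & (slope > 0.0)
            & (slope < 1.0)
            & (intercept > 0.0)
            & np.all(signals >= 0.0, axis=-1)
            & np.any(signals > 0.0, axis=-1)
            # a constant signal across flips carries no T1 information
            & (np.ptp(signals, axis=-1) > 0.0)
        )
        t1 = np.where(valid, -tr_s / np.log(np.where(valid, slope, 0.5)), np.nan)
        m0 = np.where(valid, intercept / (1.0 - np.where(valid, slope, 0.5)), np.nan)

    if nonlinear:
        flat_s = signals.reshape(-1, n)
        flat_t1 = t1.reshape(-1)
        flat_m0 = m0.reshape(-1)
        flat_valid = valid.reshape(-1)
        sin_a, cos_a = np.sin(flips), np.cos(flips)

        def resid(theta, sig):
            t1_, m0_ = theta
            e1 = np.exp(-tr_s / t1_)
            return m0_ * sin_a * (1 - e1) / (1 - e1 * cos_a) - sig

        for i in np.nonzero(flat_valid)[0]:
            sol = optimize.least_squares(
                resid,
                x0=[flat_t1[i], flat_m0[i]],
                args=(flat_s[i],),
                bounds=([1e-3, 0.0], [20.0, np.inf]),
            )
            flat_t1[i], flat_m0[i] = sol.x
        t1 = flat_t1.reshape(t1.shape)
        m0 = flat_m0.reshape(m0.shape)

    if t1.ndim == 0:
        return float(t1), float(m0), bool(valid)
    return t1, m0, valid


def _longitudinal_matrix(t1f, t1b, f, kf):
    kb = np.where(np.asarray(f, dtype=float) > 0, kf / np.where(np.asarray(f) > 0, f, 1.0), 0.0)
    a11 = -1.0 / np.asarray(t1f, dtype=float) - kf
    a22 = -1.0 / np.asarray(t1b, dtype=float) - kb
    return a11, kb, kf, a22


def observed_t1_from_two_pool(t1f, t1b, f, kf):
    """Apparent mono-exponential T1 of a two-pool system (forward map).

    Returns -1/lambda_slow where lambda_slow is the slowest (least negative)
    eigenvalue of the 2x2 longitudinal exchange-relaxation matrix.
    """
    a11, a12, a21, a22 = _longitudinal_matrix(t1f, t1b, f, kf)
    m = 0.5 * (a11 + a22)
    d = 0.5 * np.sqrt((a11 - a22) ** 2 + 4.0 * a12 * a21)
    lam_slow = m + d
    return -1.0 / lam_slow


def derive_t1f(t1_observed, f, kf, t1b=1.0):
    """Free-pool T1 consistent with an observed (apparent) T1.

    Solves for ``t1f`` such that the slowest longitudinal eigenmode of the
    exchange-relaxation matrix (rates 1/t1f, 1/t1b, kf, kb = kf/f) decays at
    ``1/t1_observed``.  The characteristic equation gives the closed form

        R1f = R1obs - kf + kf kb / (R1b + kb - R1obs).

    Returns NaN (flagged invalid) when no positive solution exists, e.g.
    when the observed rate exceeds what any positive R1f can produce.
    With ``f = 0`` (hence ``kf = 0``) the result is ``t1_observed`` exactly.
    """
    t1_observed = np.asarray(t1_observed, dtype=float)
    f = np.asarray(f, dtype=float)
    kf = np.asarray(kf, dtype=float)
    if np.any(t1_observed <= 0) or np.any(np.asarray(t1b) <= 0):
        raise ValueError("times must be strictly positive")
    if np.any(f < 0) or np.any(f >= 1) or np.any(kf < 0):
        raise ValueError("need 0 <= f < 1 and kf >= 0")
    r1obs = 1.0 / t1_observed
    r1b = 1.0 / np.asarray(t1b, dtype=float)
    kb = np.where(f > 0, kf / np.where(f > 0, f, 1.0), 0.0)
    denom = r1b + kb - r1obs
    with np.errstate(divide="ignore", invalid="ignore"):
        r1f = r1obs - kf + kf * kb / denom
        t1f = 1.0 / r1f
    ok = (denom > 0) & (r1f > 0)
    # the slow eigenvalue must indeed be -r1obs (it is, when denom > 0:
    # the other eigenvalue is then faster); guard numerically anyway
    check = observed_t1_from_two_pool(np.where(ok, t1f, 1.0), t1b, f, kf)
    ok = ok & np.isclose(check, t1_observed, rtol=1e-8)
    out = np.where(ok, t1f, np.nan)
    return float(out) if out.ndim == 0 else out
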