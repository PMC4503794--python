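"""Voxel-wise two-pool parameter estimation from the bSSFP qMT protocol.

Each masked voxel's 22-point bSSFP signal vector is fit by bounded nonlinear
least squares (damped Levenberg–Marquardt-type trust-region scheme) for the
four free parameters (M0, F, kf, T2f), with the free-pool T1 constrained by
the voxel's measured T1: either used directly (``observed_as_t1f``) or
corrected through the slowest-eigenmode relation of the longitudinal
exchange system (``eigen_corrected``, the default — a VFA measurement on a
two-pool tissue sees the apparent, not the intrinsic, free-pool T1).

The bound-pool constants T1b and T2b are not identifiable from this protocol
and are fixed (1.0 s / 12 us by convention, overridable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .relaxometry import derive_t1f
from .signal_models import AcquisitionSpec, protocol_arrays, _bssfp_signal_arrays

__all__ = ["FitOptions", "QmtMaps", "fit_qmt_voxel", "fit_qmt_volume"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitOptions:
    """Initialization, bounds and modes for the voxel-wise qMT fit.

    Bounds are (low, high) pairs; ``init_*`` values must lie inside them.
    ``m0`` is initialized per voxel from the maximum measured signal and
    bounded relative to it.
    """

    init_f: float = 0.10
    init_kf: float = 2.0
    init_t2f: float = 0.080
    bounds_f: tuple[float, float] = (0.001, 0.5)
    bounds_kf: tuple[float, float] = (0.1, 20.0)
    bounds_t2f: tuple[float, float] = (0.010, 0.300)
    m0_scale_bounds: tuple[float, float] = (0.1, 50.0)  # x max signal
    t1_mode: str = "eigen_corrected"
    t1b: float = 1.0
    t2b: float = 12e-6
    lineshape: str = "super_lorentzian"
    max_iterations: int = 200
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.t1_mode not in ("observed_as_t1f", "eigen_corrected"):
            raise ValueError(f"unknown t1_mode {self.t1_mode!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        for init, (lo, hi) in (
            (self.init_f, self.bounds_f),
            (self.init_kf, self.bounds_kf),
            (self.init_t2f, self.bounds_t2f),
        ):
            if not (lo < init < hi):
                raise ValueError(f"init value {init} outside bounds ({lo}, {hi})")


@dataclass
class QmtMaps:
    """Fitted parameter maps with per-voxel diagnostics."""

    f: np.ndarray
    kf: np.ndarray
    t2f: np.ndarray
    m0: np.ndarray
    residual_norm: np.ndarray
    converged: np.ndarray
    mask: np.ndarray

    @property
    def convergence_fraction(self) -> float:
        n_mask = int(self.mask.sum())
        if n_mask == 0:
            return float("nan")
        return float(self.converged[self.mask].sum() / n_mask)


def _model(theta, t1_obs, opts: FitOptions, arrs):
    m0, f, kf, t2f = theta
    if opts.t1_mode == "eigen_corrected":
        t1f = derive_t1f(t1_obs, f, kf, opts.t1b)
        if not np.isfinite(t1f):
            t1f = t1_obs
    else:
        t1f = t1_obs
    # t2f must stay below t1f for a physical voxel; soft-guard the model
    t2f_eff = min(t2f, 0.95 * t1f)
    return _bssfp_signal_arrays(
        m0, f, kf, t1f, opts.t1b, t2f_eff,
        arrs["w"], arrs["alpha_rad"], arrs["tr_s"], arrs["trf_s"],
    )


def fit_qmt_voxel(
    signals: np.ndarray,
    protocol: Sequence[AcquisitionSpec],
    t1_observed: float,
    opts: FitOptions = FitOptions(),
    arrs: dict | None = None,
):
    """Fit (M0, F, kf, T2f) to one voxel's bSSFP signal vector.

    Parameters
    ----------
    signals : array
        Measured magnitudes for the bssfp rows of ``protocol`` (in protocol
        order; SPGR rows, if present in ``protocol``, are ignored and
        ``signals`` must then cover only the bssfp rows).
    protocol : sequence of AcquisitionSpec
        Acquisition table; at least 4 distinct (flip, tr, trf) combinations.
    t1_observed : float
        The voxel's VFA T1 in seconds.
    arrs : dict, optional
        Precomputed :func:`protocol_arrays` output (performance path for
        volume fitting).

    Returns
    -------
    result : dict
        Keys ``m0, f, kf, t2f, residual_norm, converged, n_iterations``.
        Degenerate input (all-zero signals, invalid T1) yields
        ``converged=False`` with NaN parameters, not an exception.
    """
    if arrs is None:
        arrs = protocol_arrays(protocol, opts.lineshape, opts.t2b)
    signals = np.asarray(signals, dtype=float)
    if signals.shape != arrs["alpha_rad"].shape:
        raise ValueError(
            f"signals shape {signals.shape} does not match bssfp protocol rows "
            f"{arrs['alpha_rad'].shape}"
        )
    combos = {
        (round(a, 10), round(t, 10), round(r, 10))
        for a, t, r in zip(arrs["alpha_rad"], arrs["tr_s"], arrs["trf_s"])
    }
    if len(combos) < 4:
        raise ValueError("need >= 4 distinct (flip, tr, trf) combinations")

    invalid = dict(
        m0=np.nan, f=np.nan, kf=np.nan, t2f=np.nan,
        residual_norm=np.nan, converged=False, n_iterations=0,
    )
    if not np.all(np.isfinite(signals)) or np.max(signals) <= 0:
        return invalid
    if not (np.isfinite(t1_observed) and t1_observed > 0):
        return invalid

    s_max = float(np.max(signals))

    def resid(theta):
        return _model(theta, t1_observed, opts, arrs) - signals

    x0 = np.array([s_max / 0.15, opts.init_f, opts.init_kf, opts.init_t2f])
    lo = np.array(
        [opts.m0_scale_bounds[0] * s_max, opts.bounds_f[0], opts.bounds_kf[0], opts.bounds_t2f[0]]
    )
    hi = np.array(
        [opts.m0_scale_bounds[1] * s_max, opts.bounds_f[1], opts.bounds_kf[1], opts.bounds_t2f[1]]
    )
    x0 = np.clip(x0, lo, hi)
    sol = optimize.least_squares(
        resid,
        x0=x0,
        bounds=(lo, hi),
        method="trf",
        x_scale=np.array([s_max, 0.1, 1.0, 0.05]),
        xtol=opts.tolerance,
        ftol=opts.tolerance,
        gtol=opts.tolerance,
        max_nfev=opts.max_iterations * 5,
    )
    return dict(
        m0=float(sol.x[0]),
        f=float(sol.x[1]),
        kf=float(sol.x[2]),
        t2f=float(sol.x[3]),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.status > 0),
        n_iterations=int(sol.nfev),
    )


def fit_qmt_volume(
    data: np.ndarray,
    mask: np.ndarray,
    t1map: np.ndarray,
    protocol: Sequence[AcquisitionSpec],
    opts: FitOptions = FitOptions(),
) -> QmtMaps:
    """Independent voxel-wise qMT fit over a masked 4-D volume.

    ``data`` has shape (nx, ny, nz, n_volumes) covering the full protocol
    (bssfp rows are selected internally); ``t1map`` holds each voxel's VFA T1
    in seconds.  Voxel order does not affect results.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    t1map = np.asarray(t1map, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be 4-D (x, y, z, volume)")
    if data.shape[:3] != mask.shape or mask.shape != t1map.shape:
        raise ValueError("data, mask and t1map grids do not match")
    if data.shape[3] != len(protocol):
        raise ValueError(
            f"data has {data.shape[3]} volumes but protocol {len(protocol)} rows"
        )

    arrs = protocol_arrays(protocol, opts.lineshape, opts.t2b)
    shape = mask.shape
    out = {
        k: np.full(shape, np.nan) for k in ("f", "kf", "t2f", "m0", "residual_norm")
    }
    converged = np.zeros(shape, dtype=bool)

    idx = np.argwhere(mask)
    if idx.size == 0:
        logger.warning("empty mask: returning empty maps")
    for i, j, k in idx:
        res = fit_qmt_voxel(
            data[i, j, k, arrs["index"]], protocol, t1map[i, j, k], opts, arrs=arrs
        )
        for key in ("f", "kf", "t2f", "m0", "residual_norm"):
            out[key][i, j, k] = res[key]
        converged[i, j, k] = res["converged"]

    maps = QmtMaps(
        f=out["f"], kf=out["kf"], t2f=out["t2f"], m0=out["m0"],
        residual_norm=out["residual_norm"], converged=converged, mask=mask,
    )
    logger.info("qMT volume fit: convergence fraction %.4f", maps.convergence_fraction)
    return maps
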