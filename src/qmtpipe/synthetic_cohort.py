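"""Synthetic two-session crossover qMT study generator.

Emulates the structure of a 20-subject, vaccine-versus-placebo crossover
neuroimaging experiment: a digital phantom with gray/white/CSF classes and
insula-like plus basal-ganglia-like regions of interest, ground-truth
two-pool parameter maps with a localized forward-exchange-rate (kf) increase
injected in the left insular ROI under the inflammatory (vaccine) condition,
raw 22-volume bSSFP + 3-volume VFA image data with Rician magnitude noise,
and a behavioral table in which the fatigue change under vaccine is linearly
coupled to each subject's ROI kf change (target variance explained 24%) and
IL-6 rises roughly threefold after vaccine.

Behavioral distribution anchors (means/SDs) are generator settings chosen to
emulate the magnitudes typical of low-grade experimental inflammation
studies; they parameterize the simulation and are never claimed as outputs.

Two fidelity levels are provided:

* ``simulate_cohort`` — full raw-signal simulation (forward model + Rician
  noise) intended for end-to-end fitting tests at small grid sizes.
* ``simulate_kf_map_cohort`` — parameter-map-level simulation (ground truth
  + white map noise emulating fit error) used for replicate-heavy
  calibration studies of the group-inference machinery, where re-fitting
  every voxel of hundreds of cohorts would be pointless compute.  The map
  noise SD can be calibrated against actual fit noise with
  :func:`calibrate_kf_map_noise`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .relaxometry import observed_t1_from_two_pool
from .signal_models import (
    AcquisitionSpec,
    TwoPoolParams,
    default_protocol,
    protocol_arrays,
    spgr_signal,
    _bssfp_signal_arrays,
)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "CohortDataset",
    "DEFAULT_TISSUES",
    "build_phantom",
    "apply_condition_effect",
    "simulate_subject_session",
    "simulate_behavioral",
    "simulate_cohort",
    "simulate_kf_map_cohort",
    "simulate_uptake_maps",
    "calibrate_kf_map_noise",
]

# tissue classes: per-class two-pool parameters, typical of 1.5 T brain.
DEFAULT_TISSUES: dict[str, TwoPoolParams] = {
    "csf": TwoPoolParams(m0=1000.0, f=0.01, kf=0.5, t1f=3.5, t2f=0.25),
    "gray": TwoPoolParams(m0=820.0, f=0.10, kf=2.4, t1f=1.2, t2f=0.090),
    "white": TwoPoolParams(m0=700.0, f=0.16, kf=3.8, t1f=0.65, t2f=0.070),
}

LABELS = {"background": 0, "csf": 1, "gray": 2, "white": 3}


@dataclass(frozen=True)
class PhantomSpec:
    """Digital phantom geometry and tissue parameters.

    The brain is a three-shell ellipsoid (CSF rim, gray ribbon, white core)
    with two insula-like ellipsoidal ROIs embedded in the gray ribbon and
    two basal-ganglia-like spherical gray islands inside the white core.
    """

    shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size_mm: float = 3.0
    tissues: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    jitter_rel_sd: float = 0.0  # smooth multiplicative spatial jitter on f, kf, t2f
    snr: float = 100.0  # reference gray-matter signal over noise sigma

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if any(s < 8 for s in self.shape[:2]) or self.shape[2] < 4:
            raise ValueError("phantom grid too small to host the ROI geometry")


@dataclass(frozen=True)
class CohortSpec:
    """Study-level generator settings for the two-session crossover cohort.

    ``delta_kf_mean``/``delta_kf_sd`` define the per-subject kf increase
    (s^-1) injected in ``effect_roi`` under the vaccine condition;
    ``fatigue_r2`` is the fraction of fatigue-change variance explained by
    the subject ROI kf change.  IL-6 distributions are lognormal with
    condition/timepoint means and SDs in pmol/L.  ``kf_map_noise_sd`` is the
    white per-voxel noise of the map-level cohort mode (s^-1 per session).
    """

    n_subjects: int = 20
    delta_kf_mean: float = 0.3
    delta_kf_sd: float = 0.1
    effect_roi: str = "insula_L"
    fatigue_r2: float = 0.24
    fatigue_baseline: tuple[float, float] = (16.18, 12.57)  # vaccine mean, SD
    fatigue_change_mean: float = 26.22  # 42.40 - 16.18
    fatigue_change_sd: float = 19.4
    placebo_baseline: tuple[float, float] = (22.08, 17.72)
    placebo_change: tuple[float, float] = (7.52, 17.4)
    il6_vaccine: tuple[tuple[float, float], tuple[float, float]] = (
        (1.29, 1.70), (3.74, 1.21)
    )  # (baseline, 4h) as (mean, SD)
    il6_placebo: tuple[tuple[float, float], tuple[float, float]] = (
        (0.97, 1.03), (0.90, 0.80)
    )
    kf_map_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if not (0.0 < self.fatigue_r2 <= 1.0):
            raise ValueError("fatigue_r2 must be in (0, 1]")


@dataclass
class Phantom:
    """Realized phantom: labels, ROI masks and ground-truth parameter maps."""

    spec: PhantomSpec
    labels: np.ndarray
    rois: dict[str, np.ndarray]
    params: dict[str, np.ndarray]  # m0, f, kf, t1f, t2f per voxel
    t1b: float = 1.0
    t2b: float = 12e-6
    lineshape: str = "super_lorentzian"

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def gray_mask(self) -> np.ndarray:
        return self.labels == LABELS["gray"]


@dataclass
class CohortDataset:
    """Full synthetic study: raw volumes, ground truth and behavioral table."""

    phantom: Phantom
    cohort: CohortSpec
    protocol: list[AcquisitionSpec]
    raw: dict  # (subject, condition) -> 4-D array
    truth_kf: dict  # (subject, condition) -> 3-D array
    behavioral: pd.DataFrame
    subject_delta_kf: np.ndarray
    session_order: list[tuple[str, str]]  # per subject, session-1/session-2 condition
    provenance: dict


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def build_phantom(spec: PhantomSpec = PhantomSpec(), seed: int = 0) -> Phantom:
    """Construct the label volume, ROI masks and ground-truth maps.

    Deterministic given ``seed`` (the seed only matters when
    ``jitter_rel_sd > 0``).  Tissue classes partition the grid; every ROI is
    a subset of the gray-matter label.
    """
    nx, ny, nz = spec.shape
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    brain = _ellipsoid(spec.shape, center, (0.46 * nx, 0.46 * ny, 0.48 * nz))
    parenchyma = _ellipsoid(spec.shape, center, (0.42 * nx, 0.42 * ny, 0.44 * nz))
    white = _ellipsoid(spec.shape, center, (0.26 * nx, 0.26 * ny, 0.30 * nz))

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[brain] = LABELS["csf"]
    labels[parenchyma] = LABELS["gray"]
    labels[white] = LABELS["white"]

    rois: dict[str, np.ndarray] = {}
    # insula-like ellipsoids in the lateral gray ribbon of each hemisphere
    for name, sign in (("insula_L", -1), ("insula_R", +1)):
        c = (center[0] + sign * 0.34 * nx, center[1], center[2])
        roi = _ellipsoid(spec.shape, c, (0.09 * nx, 0.14 * ny, 0.30 * nz))
        roi &= labels == LABELS["gray"]
        if roi.sum() == 0:
            raise ValueError(f"ROI {name} fell outside the gray matter")
        rois[name] = roi
    # basal-ganglia-like gray islands inside the white core
    for name, sign in (("basal_ganglia_L", -1), ("basal_ganglia_R", +1)):
        c = (center[0] + sign * 0.13 * nx, center[1] + 0.08 * ny, center[2])
        roi = _ellipsoid(spec.shape, c, (0.07 * nx, 0.07 * ny, 0.22 * nz))
        roi &= labels == LABELS["white"]
        if roi.sum() == 0:
            raise ValueError(f"ROI {name} fell outside the white core")
        labels[roi] = LABELS["gray"]
        rois[name] = roi

    params = {k: np.zeros(spec.shape) for k in ("m0", "f", "kf", "t1f", "t2f")}
    for tissue, p in spec.tissues.items():
        m = labels == LABELS[tissue]
        params["m0"][m] = p.m0
        params["f"][m] = p.f
        params["kf"][m] = p.kf
        params["t1f"][m] = p.t1f
        params["t2f"][m] = p.t2f

    if spec.jitter_rel_sd > 0:
        rng = np.random.default_rng(seed)
        for key in ("f", "kf", "t2f"):
            noise = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 2.0)
            noise *= spec.jitter_rel_sd / max(noise.std(), 1e-12)
            params[key] = params[key] * (1.0 + noise)

    ref = spec.tissues["gray"]
    return Phantom(
        spec=spec, labels=labels, rois=rois, params=params,
        t1b=ref.t1b, t2b=ref.t2b, lineshape=ref.lineshape,
    )


def apply_condition_effect(
    params: dict[str, np.ndarray], roi: np.ndarray, delta_kf: float
) -> dict[str, np.ndarray]:
    """Return parameter maps with kf increased by ``delta_kf`` inside ``roi``.

    Every other parameter and every voxel outside the ROI is untouched;
    ``delta_kf = 0`` returns an identical copy.
    """
    if not np.isfinite(delta_kf):
        raise ValueError("delta_kf must be finite")
    roi = np.asarray(roi, dtype=bool)
    if roi.sum() == 0:
        raise ValueError("effect ROI is empty")
    out = {k: v.copy() for k, v in params.items()}
    out["kf"][roi] = out["kf"][roi] + delta_kf
    return out


def _forward_volume(
    phantom: Phantom, params: dict[str, np.ndarray],
    protocol: Sequence[AcquisitionSpec],
) -> np.ndarray:
    """Noiseless forward-modeled 4-D volume for one session."""
    mask = phantom.brain_mask
    v = {k: params[k][mask] for k in params}
    n_vox = int(mask.sum())
    out = np.zeros(phantom.spec.shape + (len(protocol),))

    bssfp = protocol_arrays(protocol, phantom.lineshape, phantom.t2b)
    sig_b = _bssfp_signal_arrays(
        v["m0"][:, None], v["f"][:, None], v["kf"][:, None],
        v["t1f"][:, None], phantom.t1b, v["t2f"][:, None],
        bssfp["w"][None, :], bssfp["alpha_rad"][None, :],
        bssfp["tr_s"][None, :], bssfp["trf_s"][None, :],
    )
    for col, row in enumerate(bssfp["index"]):
        out[..., row][mask] = sig_b[:, col]

    spgr_rows = [i for i, s in enumerate(protocol) if s.kind == "spgr"]
    if spgr_rows:
        # a VFA series on two-pool tissue sees the apparent (slow-eigenmode) T1
        t1_app = observed_t1_from_two_pool(v["t1f"], phantom.t1b, v["f"], v["kf"])
        for row in spgr_rows:
            out[..., row][mask] = spgr_signal(v["m0"], t1_app, protocol[row])
    return out


def reference_signal(phantom: Phantom, noiseless: np.ndarray,
                     protocol: Sequence[AcquisitionSpec]) -> float:
    """Noise-normalization reference: mean gray-matter bSSFP signal."""
    bssfp_rows = [i for i, s in enumerate(protocol) if s.kind == "bssfp"]
    return float(noiseless[..., bssfp_rows][phantom.gray_mask].mean())


def simulate_subject_session(
    phantom: Phantom,
    params: dict[str, np.ndarray],
    protocol: Sequence[AcquisitionSpec],
    snr: float,
    seed: int,
) -> np.ndarray:
    """Forward-model one session and add Rician magnitude noise.

    Noise sigma is (mean gray-matter bSSFP signal) / snr; ``snr = inf``
    returns the exact noiseless volume.  All outputs are non-negative
    magnitudes.
    """
    noiseless = _forward_volume(phantom, params, protocol)
    if not np.isfinite(snr):
        return noiseless
    sigma = reference_signal(phantom, noiseless, protocol) / snr
    rng = np.random.default_rng(seed)
    re = noiseless + rng.normal(0.0, sigma, noiseless.shape)
    im = rng.normal(0.0, sigma, noiseless.shape)
    return np.sqrt(re**2 + im**2)


def _lognormal_draw(rng, mean, sd, size):
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size)


def simulate_behavioral(
    cohort: CohortSpec, subject_delta_kf: np.ndarray, seed: int
) -> pd.DataFrame:
    """Behavioral table (IL-6, fatigue) for the crossover cohort.

    The vaccine fatigue change is ``b0 + b1 * delta_kf_i + eps`` with the
    slope set by the target variance fraction and the noise scaled against
    the realized sample variance of the signal component, so the cohort's
    explained-variance share fluctuates around ``fatigue_r2`` without a
    systematic calibration offset.  IL-6 is lognormal per condition and
    timepoint.  Setting ``fatigue_r2 = 1`` yields a deterministic line.
    """
    dkf = np.asarray(subject_delta_kf, dtype=float)
    n = dkf.size
    if n != cohort.n_subjects:
        raise ValueError("subject_delta_kf length must equal n_subjects")
    rng = np.random.default_rng(seed)

    sd_dkf = dkf.std(ddof=1)
    if sd_dkf <= 0:
        raise ValueError(
            "subject kf effects have zero variance: target R^2 unreachable"
        )
    r2 = cohort.fatigue_r2
    b1 = np.sqrt(r2) * cohort.fatigue_change_sd / cohort.delta_kf_sd
    b0 = cohort.fatigue_change_mean - b1 * cohort.delta_kf_mean
    signal = b1 * dkf
    v_signal = signal.var(ddof=1)
    eps = rng.standard_normal(n)
    eps -= eps.mean()
    target_v_eps = v_signal * (1.0 - r2) / r2
    if eps.std(ddof=1) > 0 and target_v_eps > 0:
        eps *= np.sqrt(target_v_eps) / eps.std(ddof=1)
    else:
        eps[:] = 0.0
    fat_change_vacc = b0 + signal + eps

    fat_base_vacc = rng.normal(*cohort.fatigue_baseline, n)
    fat_base_plac = rng.normal(*cohort.placebo_baseline, n)
    fat_change_plac = rng.normal(*cohort.placebo_change, n)

    il6 = {
        ("vaccine", "baseline"): _lognormal_draw(rng, *cohort.il6_vaccine[0], n),
        ("vaccine", "4h"): _lognormal_draw(rng, *cohort.il6_vaccine[1], n),
        ("placebo", "baseline"): _lognormal_draw(rng, *cohort.il6_placebo[0], n),
        ("placebo", "4h"): _lognormal_draw(rng, *cohort.il6_placebo[1], n),
    }
    fatigue = {
        ("vaccine", "baseline"): fat_base_vacc,
        ("vaccine", "4h"): fat_base_vacc + fat_change_vacc,
        ("placebo", "baseline"): fat_base_plac,
        ("placebo", "4h"): fat_base_plac + fat_change_plac,
    }
    rows = []
    for i in range(n):
        for cond in ("vaccine", "placebo"):
            for tp in ("baseline", "4h"):
                rows.append(
                    dict(
                        subject=f"sub-{i + 1:02d}",
                        condition=cond,
                        timepoint=tp,
                        il6=il6[(cond, tp)][i],
                        fatigue=fatigue[(cond, tp)][i],
                    )
                )
    return pd.DataFrame(rows)


def simulate_cohort(
    phantom_spec: PhantomSpec = PhantomSpec(),
    cohort: CohortSpec = CohortSpec(),
    protocol: Sequence[AcquisitionSpec] | None = None,
) -> CohortDataset:
    """Full raw-signal synthetic study (both sessions, every subject).

    Deterministic given ``cohort.seed``; the crossover session order is
    randomized per subject, and all per-subject noise streams are derived
    from the master seed.
    """
    if protocol is None:
        protocol = default_protocol()
    phantom = build_phantom(phantom_spec, seed=cohort.seed)
    rng = np.random.default_rng(cohort.seed)
    dkf = rng.normal(cohort.delta_kf_mean, cohort.delta_kf_sd, cohort.n_subjects)
    roi = phantom.rois[cohort.effect_roi]

    raw, truth_kf = {}, {}
    order = []
    for i in range(cohort.n_subjects):
        first = "vaccine" if rng.random() < 0.5 else "placebo"
        order.append((first, "placebo" if first == "vaccine" else "vaccine"))
        for cond in ("placebo", "vaccine"):
            params = phantom.params
            if cond == "vaccine":
                params = apply_condition_effect(params, roi, float(dkf[i]))
            truth_kf[(i, cond)] = params["kf"]
            noise_seed = int(
                np.random.default_rng([cohort.seed, i, cond == "vaccine"]).integers(
                    2**31
                )
            )
            raw[(i, cond)] = simulate_subject_session(
                phantom, params, protocol, phantom_spec.snr, noise_seed
            )
    behavioral = simulate_behavioral(cohort, dkf, seed=cohort.seed + 1)
    provenance = dict(
        phantom_spec={**asdict(phantom_spec), "tissues": {
            k: asdict(v) for k, v in phantom_spec.tissues.items()}},
        cohort_spec=asdict(cohort),
        seed=cohort.seed,
        n_protocol_rows=len(protocol),
    )
    return CohortDataset(
        phantom=phantom, cohort=cohort, protocol=list(protocol),
        raw=raw, truth_kf=truth_kf, behavioral=behavioral,
        subject_delta_kf=dkf, session_order=order, provenance=provenance,
    )


def simulate_kf_map_cohort(
    phantom: Phantom,
    cohort: CohortSpec,
    seed: int,
    null_effect: bool = False,
):
    """Parameter-map-level cohort: fitted-kf surrogates for both sessions.

    Each subject's per-session kf map is the ground truth (condition effect
    included unless ``null_effect``) plus white Gaussian map noise of SD
    ``cohort.kf_map_noise_sd`` within the brain mask, emulating voxel-wise
    fit error.  Returns (placebo_maps, vaccine_maps, subject_delta_kf) with
    map arrays of shape (n_subjects, nx, ny, nz).
    """
    rng = np.random.default_rng(seed)
    mask = phantom.brain_mask
    base = phantom.params["kf"]
    roi = phantom.rois[cohort.effect_roi]
    if null_effect:
        dkf = np.zeros(cohort.n_subjects)
    else:
        dkf = rng.normal(cohort.delta_kf_mean, cohort.delta_kf_sd, cohort.n_subjects)

    shape = (cohort.n_subjects,) + phantom.spec.shape
    placebo = np.broadcast_to(base, shape).copy()
    vaccine = np.broadcast_to(base, shape).copy()
    vaccine[:, roi] += dkf[:, None]
    noise = rng.normal(0.0, cohort.kf_map_noise_sd, (2,) + shape)
    placebo += noise[0] * mask
    vaccine += noise[1] * mask
    placebo[:, ~mask] = np.nan
    vaccine[:, ~mask] = np.nan
    return placebo, vaccine, dkf


def simulate_uptake_maps(
    phantom: Phantom,
    n_subjects: int,
    roi_offset: float,
    seed: int,
    fwhm_mm: float = 8.0,
    baseline: float = 50.0,
    noise_sd: float = 4.0,
    roi: str | None = None,
):
    """Smoothed-Gaussian-field uptake-like maps with an ROI offset.

    A deliberately simple stand-in for metabolic uptake images, used to
    exercise the grand-mean-scaling and exclusive-masking contrast logic:
    baseline level + smoothed noise, plus ``roi_offset`` inside the chosen
    ROI.  Returns arrays of shape (n_subjects, nx, ny, nz).
    """
    rng = np.random.default_rng(seed)
    mask = phantom.brain_mask
    sigma_vox = fwhm_mm / phantom.spec.voxel_size_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    roi_mask = phantom.rois[roi] if roi else None
    out = np.empty((n_subjects,) + phantom.spec.shape)
    for i in range(n_subjects):
        field_ = ndimage.gaussian_filter(
            rng.standard_normal(phantom.spec.shape), sigma_vox
        )
        field_ *= noise_sd / max(field_.std(), 1e-12)
        vol = baseline + field_
        if roi_mask is not None:
            vol[roi_mask] += roi_offset
        vol[~mask] = np.nan
        out[i] = vol
    return out


def calibrate_kf_map_noise(
    snr: float,
    n_rep: int = 200,
    seed: int = 0,
    tissue: TwoPoolParams | None = None,
    protocol: Sequence[AcquisitionSpec] | None = None,
) -> float:
    """Monte Carlo SD of fitted kf for one tissue at a given protocol SNR.

    Connects the raw-signal noise level to the map-level cohort mode: fits
    ``n_rep`` Rician-noised replicates of a single gray-matter voxel and
    returns the SD of the fitted kf (s^-1).
    """
    from .qmt_fit import FitOptions, fit_qmt_voxel

    tissue = tissue or DEFAULT_TISSUES["gray"]
    protocol = list(protocol) if protocol is not None else default_protocol()
    opts = FitOptions(lineshape=tissue.lineshape, t1b=tissue.t1b, t2b=tissue.t2b)
    arrs = protocol_arrays(protocol, tissue.lineshape, tissue.t2b)
    clean = _bssfp_signal_arrays(
        tissue.m0, tissue.f, tissue.kf, tissue.t1f, tissue.t1b, tissue.t2f,
        arrs["w"], arrs["alpha_rad"], arrs["tr_s"], arrs["trf_s"],
    )
    t1_obs = observed_t1_from_two_pool(tissue.t1f, tissue.t1b, tissue.f, tissue.kf)
    sigma = clean.mean() / snr
    rng = np.random.default_rng(seed)
    kfs = []
    for _ in range(n_rep):
        noisy = np.sqrt(
            (clean + rng.normal(0, sigma, clean.shape)) ** 2
            + rng.normal(0, sigma, clean.shape) ** 2
        )
        res = fit_qmt_voxel(noisy, protocol, t1_obs, opts, arrs=arrs)
        if res["converged"]:
            kfs.append(res["kf"])
    return float(np.std(kfs, ddof=1))
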