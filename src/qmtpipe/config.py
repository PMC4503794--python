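"""Declarative run configuration (YAML) binding the pipeline stages.

One config file is the single source of truth for the phantom and cohort
specs, fit options, inference settings and seeds, so a whole synthetic
study is reproducible from the file alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .qmt_fit import FitOptions
from .signal_models import TwoPoolParams
from .synthetic_cohort import CohortSpec, PhantomSpec, DEFAULT_TISSUES

__all__ = ["InferenceOptions", "RunConfig", "load_config"]


@dataclass(frozen=True)
class InferenceOptions:
    """Group-inference settings (smoothing, thresholds, Monte Carlo)."""

    fwhm_mm: float = 8.0
    p_voxel: float = 0.001
    alpha: float = 0.05
    n_iter: int = 1000
    connectivity: int = 26
    direction: str = "greater"
    match_t_field: bool = True  # df-matched Monte Carlo null

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0 or not (0 < self.p_voxel < 1) or not (0 < self.alpha < 1):
            raise ValueError("invalid inference options")


@dataclass
class RunConfig:
    """Everything needed to (re)run a synthetic study end to end."""

    output_dir: str = "qmtpipe_run"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit: FitOptions = field(default_factory=FitOptions)
    inference: InferenceOptions = field(default_factory=InferenceOptions)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"]["tissues"] = {
            k: asdict(v) if not isinstance(v, dict) else v
            for k, v in self.phantom.tissues.items()
        }
        return d


def _tissues_from_dict(d: dict) -> dict:
    return {name: TwoPoolParams(**params) for name, params in d.items()}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys raise; omitted sections fall back to package defaults.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"output_dir", "phantom", "cohort", "fit", "inference", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    phantom_kw = dict(raw.get("phantom") or {})
    if "shape" in phantom_kw:
        phantom_kw["shape"] = tuple(phantom_kw["shape"])
    if "tissues" in phantom_kw:
        phantom_kw["tissues"] = _tissues_from_dict(phantom_kw["tissues"])
    cohort_kw = dict(raw.get("cohort") or {})
    for key in ("fatigue_baseline", "placebo_baseline", "placebo_change"):
        if key in cohort_kw:
            cohort_kw[key] = tuple(cohort_kw[key])
    for key in ("il6_vaccine", "il6_placebo"):
        if key in cohort_kw:
            cohort_kw[key] = tuple(tuple(x) for x in cohort_kw[key])
    fit_kw = dict(raw.get("fit") or {})
    for key in ("bounds_f", "bounds_kf", "bounds_t2f", "m0_scale_bounds"):
        if key in fit_kw:
            fit_kw[key] = tuple(fit_kw[key])

    return RunConfig(
        output_dir=raw.get("output_dir", "qmtpipe_run"),
        phantom=PhantomSpec(**phantom_kw),
        cohort=CohortSpec(**cohort_kw),
        fit=FitOptions(**fit_kw),
        inference=InferenceOptions(**(raw.get("inference") or {})),
        seed=int(raw.get("seed", 0)),
    )
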