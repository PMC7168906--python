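"""End-to-end pipelines tying the processing stages together.

Two measurement branches produce dispersion curves that feed one common
fitting stage:

* imaging branch (SWEI): IQ frames -> Loupas displacement -> particle
  velocity at a depth row -> phase-gradient dispersion;
* torsional branch (TWE): voltage records -> crosstalk compensation ->
  time of flight -> per-frequency speeds.

``run_pipeline`` executes either branch (or both, adding the Pearson
agreement between the two curves) and emits a JSON-ready biomarker report
with a provenance block (config hash, seed, package versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field, asdict
from typing import List, Optional, Tuple

import numpy as np

from . import __version__
from .containers import DispersionCurve
from .dispersion import extract_dispersion
from .errors import ConfigError
from .fitting import confidence_band, fit_dispersion, moduli_by_frequency, pearson_agreement
from .io import fit_result_to_dict, read_container
from .motion import loupas_displacement, velocity_from_displacement
from .tof import ProbeCalibration, calibrate_delay, twe_dispersion

__all__ = ["RunConfig", "SWEIStage", "TWEStage", "FitStage", "run_pipeline"]

logger = logging.getLogger(__name__)


def _strict(cls, d: dict):
    d = dict(d)
    names = {f for f in cls.__dataclass_fields__}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class SWEIStage:
    """Imaging-branch inputs: an IQ container plus estimator settings."""

    iq: str = ""
    depth_index: Optional[int] = None  # default: NaN-median over depth rows
    kernel_depth: int = 8
    kernel_frames: int = 2
    x_range_m: Optional[Tuple[float, float]] = None
    min_amp_fraction: float = 0.1
    noise_band_hz: Optional[Tuple[float, float]] = (900.0, 2000.0)


@dataclass
class TWEStage:
    """Torsional-branch inputs: record containers plus the calibration.

    Either a known ``internal_delay_s`` or ``calibrate_against_swei=True``
    (requires the imaging branch in the same run to supply reference
    speeds) must be given.
    """

    records: List[str] = dc_field(default_factory=list)
    internal_delay_s: Optional[float] = None
    calibrate_against_swei: bool = False
    distance_m: Optional[float] = None


@dataclass
class FitStage:
    models: Tuple[str, ...] = ("kelvin_voigt", "maxwell")
    use_weights: bool = False
    n_boot: int = 0


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run (unknown keys rejected)."""

    pipeline: str = "swei"
    seed: int = 0
    rho: float = 1000.0
    band_hz: Tuple[float, float] = (200.0, 800.0)
    swei: Optional[SWEIStage] = None
    twe: Optional[TWEStage] = None
    fit: FitStage = dc_field(default_factory=FitStage)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.pipeline not in ("swei", "twe", "both"):
            raise ConfigError(f"unknown pipeline {self.pipeline!r}")
        if self.pipeline in ("swei", "both") and self.swei is None:
            raise ConfigError("swei stage configuration is required")
        if self.pipeline in ("twe", "both") and self.twe is None:
            raise ConfigError("twe stage configuration is required")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "swei" in d and d["swei"] is not None:
            d["swei"] = _strict(SWEIStage, d["swei"])
        if "twe" in d and d["twe"] is not None:
            d["twe"] = _strict(TWEStage, d["twe"])
        if "fit" in d and d["fit"] is not None:
            fd = dict(d["fit"])
            if "models" in fd:
                fd["models"] = tuple(fd["models"])
            d["fit"] = _strict(FitStage, fd)
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        return _strict(cls, d)

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


def _curve_to_dict(curve: DispersionCurve) -> dict:
    return {
        "frequency_hz": [float(f) for f in curve.f],
        "velocity_m_s": [float(c) for c in curve.c],
        "velocity_std_m_s": None if curve.c_std is None
        else [float(s) for s in curve.c_std],
        "n": None if curve.n is None else [int(n) for n in curve.n],
    }


def _swei_curve(cfg: RunConfig) -> DispersionCurve:
    iq = read_container(cfg.swei.iq)
    dmap = loupas_displacement(iq, kernel_depth=cfg.swei.kernel_depth,
                               kernel_frames=cfg.swei.kernel_frames)
    wf = velocity_from_displacement(dmap, cfg.swei.depth_index)
    curve = extract_dispersion(wf, f_band=cfg.band_hz,
                               x_range=cfg.swei.x_range_m,
                               min_amp_fraction=cfg.swei.min_amp_fraction,
                               noise_band=cfg.swei.noise_band_hz)
    if curve.empty:
        raise ConfigError("imaging branch produced an empty dispersion curve "
                          "(band outside the tracked spectrum?)")
    return curve


def _twe_curve(cfg: RunConfig, swei_curve: Optional[DispersionCurve]) -> dict:
    records = [read_container(p) for p in cfg.twe.records]
    distance = cfg.twe.distance_m or (records[0].distance if records else None)
    if cfg.twe.internal_delay_s is not None:
        cal = ProbeCalibration(internal_delay=cfg.twe.internal_delay_s,
                               distance=distance)
    elif cfg.twe.calibrate_against_swei:
        if swei_curve is None:
            raise ConfigError("calibrate_against_swei requires the imaging "
                              "branch in the same run")
        refs = [float(np.interp(r.f_exc, swei_curve.f, swei_curve.c))
                for r in records]
        cal = calibrate_delay(records, refs, distance=distance)
    else:
        raise ConfigError("torsional branch needs internal_delay_s or "
                          "calibrate_against_swei")
    curve = twe_dispersion(records, cal)
    if curve.empty:
        raise ConfigError("torsional branch produced an empty dispersion curve")
    return {"curve": curve, "calibration": cal}


def _fit_block(curve: DispersionCurve, cfg: RunConfig, seed: int) -> dict:
    weights = None
    if cfg.fit.use_weights and curve.c_std is not None and np.all(curve.c_std > 0):
        weights = 1.0 / curve.c_std**2
    out = {}
    for model in cfg.fit.models:
        fit = fit_dispersion(curve, model=model, rho=cfg.rho, weights=weights)
        block = fit_result_to_dict(fit)
        if cfg.fit.n_boot > 0:
            band = confidence_band(fit, curve, n_boot=cfg.fit.n_boot, seed=seed)
            block["band_95"] = {"frequency_hz": [float(f) for f in band.f],
                                "lo_m_s": [float(v) for v in band.lo],
                                "hi_m_s": [float(v) for v in band.hi],
                                "n_failed": band.n_failed}
        out[model] = block
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline(s) and return the biomarker report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report: dict = {"pipeline": config.pipeline}
    swei_curve = None

    if config.pipeline in ("swei", "both"):
        swei_curve = _swei_curve(config)
        report["swei"] = {
            "dispersion": _curve_to_dict(swei_curve),
            "moduli_kpa": moduli_by_frequency(swei_curve, config.rho)
            .to_dict(orient="list"),
            "fits": _fit_block(swei_curve, config, config.seed),
        }

    if config.pipeline in ("twe", "both"):
        twe = _twe_curve(config, swei_curve)
        curve = twe["curve"]
        report["twe"] = {
            "dispersion": _curve_to_dict(curve),
            "moduli_kpa": moduli_by_frequency(curve, config.rho)
            .to_dict(orient="list"),
            "fits": _fit_block(curve, config, config.seed + 1),
            "calibration": {
                "internal_delay_s": twe["calibration"].internal_delay,
                "distance_m": twe["calibration"].distance,
                "residual_std_s": twe["calibration"].residual_std,
            },
        }
        if swei_curve is not None:
            try:
                r, pairs = pearson_agreement(swei_curve, curve)
                report["pearson_r"] = r
                report["pearson_pairs_hz"] = pairs.tolist()
            except ConfigError as exc:
                report["pearson_r"] = None
                logger.warning("Pearson agreement unavailable: %s", exc)

    import numpy as _np
    import scipy as _sp
    report["provenance"] = {
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"swelast": __version__, "numpy": _np.__version__,
                     "scipy": _sp.__version__},
    }
    return report
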