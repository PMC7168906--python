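"""Persistent formats: ``.npz`` array containers, dispersion-curve CSV,
fit-result JSON and medium config files.

The array container is a NumPy ``.npz`` holding the named arrays of one
core object plus a JSON metadata block (``__meta__``) recording the schema
name, container version and scalar metadata.  Round trips are lossless.
Dispersion curves travel as CSV with frozen headers (units in the names):
``frequency_hz, velocity_m_s, velocity_std_m_s, n``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .containers import (
    DisplacementMap,
    DispersionCurve,
    IQSequence,
    TWERecord,
    WaveField,
)
from .errors import SchemaError

__all__ = [
    "write_container",
    "read_container",
    "write_curve_csv",
    "read_curve_csv",
    "write_inspection_csv",
    "fit_result_to_dict",
    "write_fit_json",
]

CONTAINER_VERSION = 1

PathLike = Union[str, Path]


def write_container(path: PathLike, obj) -> None:
    """Write a core data object to a ``.npz`` container with JSON metadata."""
    arrays = {}
    meta = {"version": CONTAINER_VERSION}
    if isinstance(obj, WaveField):
        meta["schema"] = "wavefield"
        arrays = {"x": obj.x, "t": obj.t, "v": obj.v}
    elif isinstance(obj, IQSequence):
        meta["schema"] = "iq"
        meta.update(fc=obj.fc, fs=obj.fs, pri=obj.pri, c0=obj.c0)
        arrays = {"iq": obj.iq}
        if obj.x is not None:
            arrays["x"] = obj.x
    elif isinstance(obj, TWERecord):
        meta["schema"] = "twe_record"
        meta.update(f_exc=obj.f_exc, distance=obj.distance,
                    n_averages=obj.n_averages)
        arrays = {"t": obj.t, "v_specimen": obj.v_specimen, "v_air": obj.v_air}
    elif isinstance(obj, DisplacementMap):
        meta["schema"] = "displacement"
        meta.update(pri=obj.pri, cumulative=obj.cumulative)
        arrays = {"d": obj.d}
        if obj.x is not None:
            arrays["x"] = obj.x
        if obj.depth is not None:
            arrays["depth"] = obj.depth
    else:
        raise SchemaError(f"cannot serialize object of type {type(obj).__name__}")
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def read_container(path: PathLike):
    """Read a ``.npz`` container back into its typed data object."""
    with np.load(path) as npz:
        if "__meta__" not in npz:
            raise SchemaError(f"{path}: not a swelast container (missing metadata)")
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        version = meta.get("version")
        if version != CONTAINER_VERSION:
            raise SchemaError(
                f"{path}: unsupported container version {version!r} "
                f"(this build reads version {CONTAINER_VERSION})"
            )
        schema = meta.get("schema")
        data = {k: npz[k] for k in npz.files if k != "__meta__"}
    if schema == "wavefield":
        return WaveField(x=data["x"], t=data["t"], v=data["v"])
    if schema == "iq":
        return IQSequence(iq=data["iq"], fc=meta["fc"], fs=meta["fs"],
                          pri=meta["pri"], c0=meta["c0"], x=data.get("x"))
    if schema == "twe_record":
        return TWERecord(t=data["t"], v_specimen=data["v_specimen"],
                         v_air=data["v_air"], f_exc=meta["f_exc"],
                         distance=meta["distance"],
                         n_averages=meta["n_averages"])
    if schema == "displacement":
        return DisplacementMap(d=data["d"], pri=meta["pri"],
                               cumulative=meta["cumulative"],
                               x=data.get("x"), depth=data.get("depth"))
    raise SchemaError(f"{path}: unknown container schema {schema!r}")


_CURVE_REQUIRED = ["frequency_hz", "velocity_m_s"]


def write_curve_csv(path: PathLike, curve: DispersionCurve) -> None:
    """Write a dispersion curve as CSV with the frozen header layout."""
    df = pd.DataFrame({
        "frequency_hz": curve.f,
        "velocity_m_s": curve.c,
        "velocity_std_m_s": curve.c_std if curve.c_std is not None
        else np.full(curve.f.shape, np.nan),
        "n": curve.n if curve.n is not None else np.ones(curve.f.shape, int),
    })
    df.to_csv(path, index=False)


def read_curve_csv(path: PathLike) -> DispersionCurve:
    """Read a dispersion-curve CSV, validating the required columns."""
    df = pd.read_csv(path)
    for col in _CURVE_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    c_std = df["velocity_std_m_s"].to_numpy() if "velocity_std_m_s" in df else None
    n = df["n"].to_numpy() if "n" in df else None
    return DispersionCurve(f=df["frequency_hz"].to_numpy(),
                           c=df["velocity_m_s"].to_numpy(), c_std=c_std, n=n)


def write_inspection_csv(path: PathLike, obj) -> None:
    """Flat CSV view of a wavefield or torsional-wave record, for eyeballing.

    Wavefields: one row per time sample, one ``v_x<i>_m_s`` column per
    lateral position.  Records: time, specimen (averaged) and air traces.
    """
    if isinstance(obj, WaveField):
        df = pd.DataFrame(obj.v.T,
                          columns=[f"v_x{i}_m_s" for i in range(obj.x.size)])
        df.insert(0, "time_s", obj.t)
    elif isinstance(obj, TWERecord):
        v = obj.v_specimen
        if v.ndim == 2:
            v = v.mean(axis=0)
        df = pd.DataFrame({"time_s": obj.t, "v_specimen": v,
                           "v_air": obj.v_air})
    else:
        raise SchemaError(
            f"no CSV inspection view for {type(obj).__name__}")
    df.to_csv(path, index=False)


def fit_result_to_dict(fit) -> dict:
    """Fit result as a JSON-ready dict with kPa / Pa*s at the boundary."""
    p = fit.params
    if fit.model == "kelvin_voigt":
        params = {"mu_kpa": p.mu / 1e3, "eta_pa_s": p.eta}
        ci = {"mu_kpa": [v / 1e3 for v in fit.ci95["mu"]],
              "eta_pa_s": list(fit.ci95["eta"])}
    else:
        params = {"mu1_kpa": p.mu1 / 1e3, "mu2_pa_s": p.mu2}
        ci = {"mu1_kpa": [v / 1e3 for v in fit.ci95["mu1"]],
              "mu2_pa_s": list(fit.ci95["mu2"])}
    return {
        "model": fit.model,
        "rho_kg_m3": fit.rho,
        "params": params,
        "ci95": ci,
        "r_squared": fit.r_squared,
        "flagged": fit.flagged,
        "residuals_m_s": [float(r) for r in fit.residuals],
        "frequency_hz": [float(f) for f in fit.f],
    }


def write_fit_json(path: PathLike, fit) -> None:
    with open(path, "w") as fh:
        json.dump(fit_result_to_dict(fit), fh, indent=2)
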