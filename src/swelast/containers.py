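"""Core in-memory data containers shared by the processing stages.

These are thin validated dataclasses around NumPy arrays; the persistent
representation (``.npz`` container with a JSON metadata block, CSV for
dispersion curves) lives in :mod:`swelast.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError

__all__ = [
    "WaveField",
    "IQSequence",
    "TWERecord",
    "DisplacementMap",
    "PhaseMap",
    "DispersionCurve",
]


def _check_uniform_grid(g: np.ndarray, name: str) -> None:
    if g.ndim != 1 or g.size < 2:
        raise ConfigError(f"{name} grid must be 1-D with >= 2 samples")
    d = np.diff(g)
    if np.any(d <= 0):
        raise ConfigError(f"{name} grid must be strictly increasing")
    if not np.allclose(d, d[0], rtol=1e-6, atol=0.0):
        raise ConfigError(f"{name} grid must be uniform")


@dataclass
class WaveField:
    """Particle-velocity field ``v(x, t)`` of a laterally propagating shear wave.

    ``x``: lateral positions (m, uniform); ``t``: slow-time samples (s,
    uniform); ``v``: particle velocity, shape ``(len(x), len(t))`` in m/s.
    """

    x: np.ndarray
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        _check_uniform_grid(self.x, "lateral")
        _check_uniform_grid(self.t, "time")
        if self.v.shape != (self.x.size, self.t.size):
            raise ConfigError(
                f"v must have shape (len(x), len(t)) = {(self.x.size, self.t.size)}, "
                f"got {self.v.shape}"
            )
        if not np.all(np.isfinite(self.v)):
            raise ConfigError("wavefield contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])


@dataclass
class IQSequence:
    """Complex demodulated (IQ) ultrasound frame ensemble.

    ``iq``: complex samples, shape (depth, lateral, frame).
    ``fc``: tracking center frequency, Hz.  ``fs``: axial sampling frequency,
    Hz.  ``pri``: pulse repetition interval between frames, s.  ``c0``:
    assumed sound speed, m/s.  ``x``: optional lateral positions, m.
    """

    iq: np.ndarray
    fc: float
    fs: float
    pri: float
    c0: float = 1540.0
    x: Optional[np.ndarray] = None

    def __post_init__(self):
        self.iq = np.asarray(self.iq, dtype=complex)
        if self.iq.ndim != 3:
            raise ConfigError("iq must be a (depth, lateral, frame) array")
        if self.iq.shape[2] < 2:
            raise ConfigError("IQ sequence needs at least 2 frames")
        if not self.pri > 0:
            raise ConfigError("pri must be > 0")
        if not (self.fc > 0 and self.fs > 0 and self.c0 > 0):
            raise ConfigError("fc, fs and c0 must be > 0")
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
            if self.x.size != self.iq.shape[1]:
                raise ConfigError("x must match the lateral dimension of iq")

    @property
    def n_frames(self) -> int:
        return self.iq.shape[2]

    @property
    def depth(self) -> np.ndarray:
        """Depth grid implied by fs and c0 (pulse-echo), m."""
        return np.arange(self.iq.shape[0]) * self.c0 / (2.0 * self.fs)


@dataclass
class TWERecord:
    """Torsional-wave received-voltage record plus its air reference.

    ``v_specimen`` may be 1-D (already averaged) or 2-D ``(n_averages, nt)``
    (individual repetitions); ``v_air`` is the crosstalk reference taken in
    air, sharing the time base ``t``.
    """

    t: np.ndarray
    v_specimen: np.ndarray
    v_air: np.ndarray
    f_exc: float
    distance: float
    n_averages: int = 1

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v_specimen = np.asarray(self.v_specimen, dtype=float)
        self.v_air = np.asarray(self.v_air, dtype=float)
        _check_uniform_grid(self.t, "time")
        if self.v_specimen.shape[-1] != self.t.size:
            raise ConfigError("v_specimen must share the time base with t")
        if self.v_air.shape != self.t.shape:
            raise ConfigError("v_air must share the time base with t")
        if self.v_specimen.ndim == 2:
            self.n_averages = self.v_specimen.shape[0]
        elif self.v_specimen.ndim != 1:
            raise ConfigError("v_specimen must be 1-D or (n_averages, nt)")
        if not self.f_exc > 0:
            raise ConfigError("f_exc must be > 0")
        if not self.distance > 0:
            raise ConfigError("distance must be > 0")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class DisplacementMap:
    """Axial displacement estimates on a depth x lateral x frame grid (m).

    Frame count is one less than the source IQ sequence (inter-frame
    estimates); when ``cumulative`` the frames hold running sums of the
    inter-frame estimates relative to the first (pre-push) frame.
    """

    d: np.ndarray
    pri: float
    cumulative: bool = True
    x: Optional[np.ndarray] = None
    depth: Optional[np.ndarray] = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 3:
            raise ConfigError("d must be a (depth, lateral, frame) array")
        if not self.pri > 0:
            raise ConfigError("pri must be > 0")


@dataclass
class PhaseMap:
    """Unwrapped spectral phase ``phi(x, omega)`` and amplitude of a wavefield.

    ``phi`` and ``amp`` have shape ``(len(x), len(omega))``; ``phi`` is
    unwrapped along ``x`` within each frequency bin.
    """

    omega: np.ndarray
    x: np.ndarray
    phi: np.ndarray
    amp: np.ndarray

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.amp = np.asarray(self.amp, dtype=float)
        shape = (self.x.size, self.omega.size)
        if self.phi.shape != shape or self.amp.shape != shape:
            raise ConfigError("phi and amp must have shape (len(x), len(omega))")


@dataclass
class DispersionCurve:
    """Phase-velocity dispersion samples: ``c`` (m/s) at frequencies ``f`` (Hz).

    The common currency between the imaging (SWEI) and torsional-wave (TWE)
    branches and the rheological fitting stage.  ``c_std`` is the spread
    (standard deviation or regression standard error) and ``n`` the number of
    samples behind each point.
    """

    f: np.ndarray
    c: np.ndarray
    c_std: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.f.ndim != 1 or self.c.shape != self.f.shape:
            raise ConfigError("f and c must be matching 1-D arrays")
        if self.f.size and np.any(np.diff(self.f) <= 0):
            raise ConfigError("f must be strictly increasing")
        if self.f.size and np.any(self.c <= 0):
            raise ConfigError("velocities must be > 0")
        if self.c_std is not None:
            self.c_std = np.asarray(self.c_std, dtype=float)
            if self.c_std.shape != self.f.shape:
                raise ConfigError("c_std must match f")
        if self.n is not None:
            self.n = np.asarray(self.n, dtype=int)
            if self.n.shape != self.f.shape:
                raise ConfigError("n must match f")

    @property
    def empty(self) -> bool:
        return self.f.size == 0

    def __len__(self) -> int:
        return self.f.size
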