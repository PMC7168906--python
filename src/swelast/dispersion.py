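"""Phase-gradient dispersion extraction from a propagating shear wavefield.

For a monochromatic plane wave travelling along x the spectral phase is
``phi(x, omega) = -Re k(omega) * x``: the real wavenumber at each frequency
is the (negated) slope of the unwrapped phase versus propagation distance,
and the phase velocity follows as ``c(omega) = omega / Re k(omega)``.

The pipeline is: temporal Fourier transform of ``v(x, t)`` per lateral
position, phase unwrapping along x within each frequency bin, amplitude
masking of weak bins/positions, and an ordinary least-squares line fit of
phase against x per retained bin.  Bins failing the amplitude or regression
quality filters are dropped, never interpolated.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple, Union

import numpy as np
from scipy import stats

from .containers import DispersionCurve, PhaseMap, WaveField
from .errors import ConfigError

__all__ = ["compute_phase_map", "fit_phase_slope", "extract_dispersion"]

logger = logging.getLogger(__name__)

Smoothing = Optional[Tuple[str, int]]


def _smooth_time(v: np.ndarray, smoothing: Smoothing) -> np.ndarray:
    """Smooth along slow time with a normalized window (same for every x).

    Implemented as circular convolution, so every lateral position's
    spectrum is multiplied by one common transfer function: smoothing
    changes amplitude and absolute phase but never the phase *slope*
    along x.
    """
    if smoothing is None:
        return v
    kind, n = smoothing
    n = int(n)
    nt = v.shape[1]
    if n < 1 or n > nt:
        raise ConfigError(f"smoothing window {n} outside the record")
    if kind == "boxcar":
        w = np.ones(n)
    elif kind == "hann":
        w = np.hanning(n + 2)[1:-1]
    else:
        raise ConfigError(f"unknown smoothing window {kind!r}")
    kernel = np.zeros(nt)
    kernel[:n] = w / w.sum()
    kernel = np.roll(kernel, -(n // 2))
    return np.fft.irfft(np.fft.rfft(v, axis=1) * np.fft.rfft(kernel)[None, :],
                        n=nt, axis=1)


def compute_phase_map(
    field: WaveField,
    smoothing: Smoothing = None,
    window: str = "rect",
    zero_pad: int = 1,
) -> PhaseMap:
    """Temporal spectrum of a wavefield with phase unwrapped along x.

    ``window`` ("rect" or "hann") tapers the slow-time record before the
    FFT; ``zero_pad`` multiplies the FFT length for finer bin placement.
    The default rectangular window is exact for sources synthesized on DFT
    bins; windowing and padding only reshape amplitude leakage and add a
    per-bin constant phase, leaving the slope along x untouched.
    """
    if field.t.size < 8:
        raise ConfigError("need at least 8 time samples")
    if field.x.size < 4:
        raise ConfigError("need at least 4 lateral positions")
    if zero_pad < 1:
        raise ConfigError("zero_pad must be >= 1")

    v = _smooth_time(field.v, smoothing)
    nt = field.t.size
    if window == "rect":
        w = np.ones(nt)
    elif window == "hann":
        w = np.hanning(nt)
    else:
        raise ConfigError(f"unknown temporal window {window!r}")

    nfft = nt * int(zero_pad)
    spec = np.fft.rfft(v * w[None, :], n=nfft, axis=1)
    omega = 2.0 * np.pi * np.fft.rfftfreq(nfft, d=field.dt)
    phi = np.unwrap(np.angle(spec), axis=0)
    return PhaseMap(omega=omega, x=field.x.copy(), phi=phi, amp=np.abs(spec))


def fit_phase_slope(
    pmap: PhaseMap,
    omega_bin: Union[int, float],
    x_range: Optional[Tuple[float, float]] = None,
    min_amp_fraction: float = 0.1,
    extra_mask: Optional[np.ndarray] = None,
):
    """Least-squares wavenumber at one frequency bin.

    ``omega_bin`` is either a bin index (int) or an angular frequency in
    rad/s (float; nearest bin is used).  Positions outside ``x_range`` or
    with spectral amplitude below ``min_amp_fraction`` of the bin's maximum
    are excluded.  Returns ``(k_re, k_stderr, n_used)`` where ``k_re`` is
    the negated phase slope (rad/m), or ``None`` when fewer than 3 usable
    positions remain.
    """
    if isinstance(omega_bin, (int, np.integer)):
        b = int(omega_bin)
    else:
        b = int(np.argmin(np.abs(pmap.omega - float(omega_bin))))
    amp = pmap.amp[:, b]
    mask = amp >= min_amp_fraction * amp.max() if amp.max() > 0 else np.zeros_like(amp, bool)
    if x_range is not None:
        mask &= (pmap.x >= x_range[0]) & (pmap.x <= x_range[1])
    if extra_mask is not None:
        mask &= extra_mask
    n_used = int(mask.sum())
    if n_used < 3:
        logger.debug("bin %d dropped: %d usable positions", b, n_used)
        return None
    res = stats.linregress(pmap.x[mask], pmap.phi[mask, b])
    return -res.slope, res.stderr, n_used


def extract_dispersion(
    field: WaveField,
    f_band: Tuple[float, float] = (200.0, 800.0),
    x_range: Optional[Tuple[float, float]] = None,
    min_amp_fraction: float = 0.1,
    smoothing: Smoothing = None,
    window: str = "rect",
    zero_pad: int = 1,
    max_rel_stderr: float = 0.25,
    noise_band: Optional[Tuple[float, float]] = None,
    noise_mult: float = 3.0,
) -> DispersionCurve:
    """Phase-velocity dispersion curve of a wavefield over ``f_band`` (Hz).

    Frequency bins are retained when their peak spectral amplitude reaches
    ``min_amp_fraction`` of the global maximum within the band; each
    retained bin's velocity is ``c = omega / |Re k|`` from the phase-slope
    fit (the magnitude makes the estimate invariant to the propagation
    direction), with the regression standard error propagated to ``c_std``.
    Bins whose fit fails, whose relative slope error exceeds
    ``max_rel_stderr``, or whose slope is zero are dropped.  An empty curve
    (no retained bins) is returned as a zero-length :class:`DispersionCurve`.

    ``noise_band`` (Hz) activates a per-bin noise gate for estimated (noisy)
    fields: each position's noise-floor amplitude is taken as its median
    spectral amplitude over that out-of-band interval — the region where
    source energy is absent and everything is noise — and positions whose
    in-band amplitude is below ``noise_mult`` times their floor are excluded
    from the slope fit (their phase is meaningless).
    """
    nyq = 0.5 / field.dt
    if not (0.0 < f_band[0] < f_band[1] < nyq):
        raise ConfigError(f"f_band {f_band} outside (0, Nyquist={nyq:.1f}) Hz")

    pmap = compute_phase_map(field, smoothing=smoothing, window=window,
                             zero_pad=zero_pad)
    f_all = pmap.omega / (2.0 * np.pi)
    in_band = (f_all >= f_band[0]) & (f_all <= f_band[1])
    if not np.any(in_band):
        return DispersionCurve(f=np.array([]), c=np.array([]))

    # bin retention threshold is relative to the spectrum's global peak so
    # that bands containing only numerical/measurement noise come out empty
    peak_amp = pmap.amp.max(axis=0)
    global_max = peak_amp.max()
    if global_max <= 0:
        return DispersionCurve(f=np.array([]), c=np.array([]))
    candidate = np.flatnonzero(in_band & (peak_amp >= min_amp_fraction * global_max))

    noise_floor = None
    if noise_band is not None:
        nb = (f_all >= noise_band[0]) & (f_all <= noise_band[1])
        if np.any(nb):
            noise_floor = np.median(pmap.amp[:, nb], axis=1)

    fs, cs, stds, ns = [], [], [], []
    dropped = 0
    for b in candidate:
        extra = None
        if noise_floor is not None:
            extra = pmap.amp[:, b] >= noise_mult * noise_floor
        fit = fit_phase_slope(pmap, int(b), x_range=x_range,
                              min_amp_fraction=min_amp_fraction,
                              extra_mask=extra)
        if fit is None:
            dropped += 1
            continue
        k_re, k_err, n_used = fit
        k_mag = abs(k_re)
        if k_mag == 0.0 or (k_err is not None and k_err / k_mag > max_rel_stderr):
            dropped += 1
            continue
        omega = pmap.omega[b]
        fs.append(omega / (2.0 * np.pi))
        cs.append(omega / k_mag)
        stds.append(omega / k_mag**2 * k_err)
        ns.append(n_used)
    if dropped:
        logger.info("dropped %d of %d candidate bins", dropped, candidate.size)
    if not fs:
        return DispersionCurve(f=np.array([]), c=np.array([]))
    return DispersionCurve(f=np.array(fs), c=np.array(cs),
                           c_std=np.array(stds), n=np.array(ns))
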