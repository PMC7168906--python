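"""Axial tissue-motion estimation from IQ ensembles (imaging branch front end).

The displacement between successive tracking frames is recovered from the
phase of the slow-time lag-one 2-D autocorrelation of the complex IQ data.
The estimator follows Loupas' 2-D autocorrelator: the phase is converted to
displacement using the *estimated* echo center frequency (from the fast-time
lag-one autocorrelation) rather than the nominal demodulation frequency,
which removes the bias the plain Kasai estimator incurs when the echo
spectrum is shifted.  Displacements are signed, positive away from the
transducer (depth increasing downward).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .containers import DisplacementMap, IQSequence, WaveField
from .errors import ConfigError

__all__ = ["loupas_displacement", "velocity_from_displacement"]


def _window_starts(n: int, m: int) -> np.ndarray:
    """Centred length-m window start index per sample, clipped to the array."""
    return np.clip(np.arange(n) - m // 2, 0, n - m)


def loupas_displacement(
    iq: IQSequence,
    kernel_depth: int = 8,
    kernel_frames: int = 2,
    method: str = "loupas",
    cumulative: bool = True,
    min_coherence: float = 0.0,
) -> DisplacementMap:
    """Estimate axial displacement from an IQ frame ensemble.

    Parameters
    ----------
    iq
        Complex IQ frames, (depth, lateral, frame).
    kernel_depth, kernel_frames
        Averaging kernel: M axial samples by N slow-time frames (M, N >= 2).
        Depth windows are centred and clipped at the edges so the output
        keeps the input depth grid.
    method
        ``"loupas"`` applies the fast-time center-frequency correction;
        ``"kasai"`` uses the nominal ``fc`` (uncorrected fallback).
    cumulative
        Return running sums of the inter-frame estimates relative to the
        first frame (the pre-push reference); otherwise raw inter-frame
        increments.
    min_coherence
        Quality gate: windows whose normalized slow-time autocorrelation
        magnitude ``|R1| / sqrt(P_n P_n+1)`` falls below this value are
        reported as NaN (destructive speckle or noise-dominated windows
        whose phase is meaningless).  0 disables the gate.

    Returns
    -------
    DisplacementMap
        ``n_frames - 1`` frames of displacement in metres.  The per-pair
        estimate is ``-(c0 / (4 pi fc_hat)) * arg R1_slow`` and is therefore
        unambiguous only for inter-frame shifts below ``c0/(4 fc)`` (quarter
        wavelength); larger shifts wrap.  Windows with zero autocorrelation
        magnitude yield NaN.
    """
    m, n_ens = int(kernel_depth), int(kernel_frames)
    if m < 2 or n_ens < 2:
        raise ConfigError("kernel must be at least 2 depth samples x 2 frames")
    nz, nx, nf = iq.iq.shape
    if m > nz or n_ens > nf:
        raise ConfigError(
            f"kernel {m}x{n_ens} does not fit the {nz}x{nf} (depth x frame) data"
        )
    if method not in ("loupas", "kasai"):
        raise ConfigError(f"unknown motion estimator {method!r}")

    q = iq.iq
    # lag-one products: slow time (frame pairs) and fast time (depth pairs)
    p_slow = np.conj(q[:, :, :-1]) * q[:, :, 1:]          # (nz, nx, nf-1)
    p_fast = np.conj(q[:-1, :, :]) * q[1:, :, :]          # (nz-1, nx, nf)

    # ensemble start per inter-frame index: window of n_ens frames holding
    # the pair, clipped at the end of the record
    starts = np.minimum(np.arange(nf - 1), nf - n_ens)

    # slow-time sums over the ensemble's n_ens-1 pairs, then depth windows
    cs_slow = np.concatenate(
        [np.zeros((nz, nx, 1), dtype=complex), np.cumsum(p_slow, axis=2)], axis=2
    )
    rs_frames = cs_slow[:, :, starts + n_ens - 1] - cs_slow[:, :, starts]
    cs_fast = np.concatenate(
        [np.zeros((nz - 1, nx, 1), dtype=complex), np.cumsum(p_fast, axis=2)], axis=2
    )
    rf_frames = cs_fast[:, :, starts + n_ens] - cs_fast[:, :, starts]

    # centred, clipped depth windows: M samples for slow time, M-1 pairs for
    # fast time, realised through cumulative sums along depth
    ws = _window_starts(nz, m)
    cz_slow = np.concatenate(
        [np.zeros((1, nx, nf - 1), dtype=complex), np.cumsum(rs_frames, axis=0)], axis=0
    )
    rs = cz_slow[ws + m] - cz_slow[ws]
    ws_f = np.clip(ws, 0, nz - m)  # fast-time pairs live inside the same window
    cz_fast = np.concatenate(
        [np.zeros((1, nx, nf - 1), dtype=complex), np.cumsum(rf_frames, axis=0)], axis=0
    )
    rf = cz_fast[ws_f + m - 1] - cz_fast[ws_f]

    theta_slow = np.angle(rs)
    if method == "loupas":
        # estimated local center frequency: nominal fc plus the deviation
        # measured by the fast-time lag-one phase on the demodulated data;
        # implausible deviations (beyond half the nominal frequency, i.e.
        # far outside the echo bandwidth — destructive-speckle or
        # noise-only windows) fall back to fc
        f_hat = iq.fc + np.angle(rf) * iq.fs / (2.0 * np.pi)
        f_hat = np.where(np.abs(f_hat - iq.fc) > 0.5 * iq.fc, iq.fc, f_hat)
    else:
        f_hat = iq.fc

    d = -(iq.c0 / (4.0 * np.pi)) * theta_slow / f_hat
    d = np.where(np.abs(rs) == 0.0, np.nan, d)
    if min_coherence > 0.0:
        # normalized coherence of the slow-time autocorrelation over the
        # same window: Cauchy-Schwarz bounds it by 1; low values flag
        # windows whose phase carries no displacement information
        pw = np.abs(q) ** 2
        cs_pw = np.concatenate(
            [np.zeros((nz, nx, 1)), np.cumsum(pw, axis=2)], axis=2
        )
        pa_frames = cs_pw[:, :, starts + n_ens - 1] - cs_pw[:, :, starts]
        pb_frames = cs_pw[:, :, starts + n_ens] - cs_pw[:, :, starts + 1]
        cz_pa = np.concatenate(
            [np.zeros((1, nx, nf - 1)), np.cumsum(pa_frames, axis=0)], axis=0
        )
        cz_pb = np.concatenate(
            [np.zeros((1, nx, nf - 1)), np.cumsum(pb_frames, axis=0)], axis=0
        )
        pa = cz_pa[ws + m] - cz_pa[ws]
        pb = cz_pb[ws + m] - cz_pb[ws]
        denom = np.sqrt(pa * pb)
        coherence = np.divide(np.abs(rs), denom, out=np.zeros_like(denom),
                              where=denom > 0)
        d = np.where(coherence >= min_coherence, d, np.nan)
    if cumulative:
        # NaN increments (masked or degenerate windows) accumulate as zero
        # motion so the running sum stays usable for display
        d = np.nancumsum(d, axis=2)

    return DisplacementMap(d=d, pri=iq.pri, cumulative=cumulative, x=iq.x,
                           depth=iq.depth)


def velocity_from_displacement(
    dmap: DisplacementMap,
    depth_index: Optional[int] = None,
    pri: Optional[float] = None,
) -> WaveField:
    """Particle-velocity field from a displacement map.

    Inter-frame displacement is already a per-PRI difference, so
    ``v = d_interframe / pri``; cumulative maps are first differenced.
    ``depth_index`` selects one depth row; ``None`` (default) takes the
    NaN-ignoring median across the depth rows of the region of interest,
    which suppresses the destructive-speckle outliers any single row
    carries.  Residual NaNs are replaced by zero velocity.
    """
    pri = dmap.pri if pri is None else pri
    if not pri > 0:
        raise ConfigError("pri must be > 0")
    nz = dmap.d.shape[0]
    if depth_index is not None and not (-nz <= depth_index < nz):
        raise ConfigError(f"depth_index {depth_index} outside 0..{nz - 1}")
    d3 = dmap.d
    if dmap.cumulative:
        d3 = np.diff(d3, axis=2, prepend=0.0)
    if depth_index is None:
        with np.errstate(invalid="ignore"):
            d = np.nanmedian(d3, axis=0)  # (lateral, frame)
    else:
        d = d3[depth_index]
    v = np.nan_to_num(d / pri)
    x = dmap.x if dmap.x is not None else np.arange(d.shape[0], dtype=float)
    t = (np.arange(d.shape[1]) + 1) * pri
    return WaveField(x=x, t=t, v=v)
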