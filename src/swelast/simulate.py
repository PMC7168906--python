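"""Synthetic data generators for both elastography branches.

Stands in for the acquisition hardware at desk scale: a dispersive plane
shear wavefield in a viscoelastic medium, scatterer-based IQ tracking frames
for the imaging (SWEI) branch, and torsional-wave (TWE) voltage records with
internal probe delay and electromechanical crosstalk.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .containers import IQSequence, TWERecord, WaveField
from .errors import ConfigError
from .rheology import Medium, attenuation, phase_velocity, wavenumber

__all__ = [
    "IQProbe",
    "tone_comb",
    "simulate_wavefield",
    "simulate_iq",
    "simulate_twe",
    "burst_waveform",
    "wavefield_to_displacement",
]

# A source spectrum is a mapping {frequency_hz: amplitude_m_s} or a sequence
# of (frequency_hz, amplitude_m_s[, phase_rad]) tuples.
SourceSpectrum = Union[Mapping[float, float], Sequence[Tuple[float, ...]]]


def tone_comb(
    f_lo: float = 200.0,
    f_hi: float = 800.0,
    spacing: float = 50.0,
    amplitude: float = 5e-3,
) -> dict:
    """Equal-amplitude tone comb covering the working band (default 200–800 Hz).

    With a slow-time record of duration ``n/spacing`` seconds the tones fall
    on exact DFT bins, which keeps the spectral analysis leakage-free.
    """
    freqs = np.arange(f_lo, f_hi + 0.5 * spacing, spacing)
    return {float(f): amplitude for f in freqs}


def _normalize_spectrum(source: SourceSpectrum):
    if isinstance(source, Mapping):
        items = [(float(f), float(a), 0.0) for f, a in sorted(source.items())]
    else:
        items = []
        for entry in source:
            if len(entry) == 2:
                f, a = entry
                phi = 0.0
            else:
                f, a, phi = entry
            items.append((float(f), float(a), float(phi)))
    if not items:
        raise ConfigError("source spectrum is empty")
    return items


def simulate_wavefield(
    medium: Medium,
    x: np.ndarray,
    t: np.ndarray,
    source: SourceSpectrum,
    noise_snr_db: Optional[float] = None,
    seed: int = 0,
    cylindrical_spreading: bool = False,
) -> WaveField:
    """Synthesize a plane shear wave propagating in +x through ``medium``.

    Each spectral component of amplitude ``A`` at angular frequency ``omega``
    contributes ``A * exp(-alpha(omega) x) * cos(omega t - Re k(omega) x + phi0)``,
    so the field carries exactly the medium's dispersion and attenuation.
    White Gaussian noise is added at ``noise_snr_db`` relative to the peak
    field amplitude.  1-D lateral propagation (no diffraction) by default;
    ``cylindrical_spreading`` adds a 1/sqrt(x) geometric decay referenced to
    the first lateral position.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    tones = _normalize_spectrum(source)
    dt = t[1] - t[0]
    nyquist = 0.5 / dt
    for f, _, _ in tones:
        if f <= 0 or f >= nyquist:
            raise ConfigError(
                f"source tone at {f} Hz outside (0, Nyquist={nyquist:.1f} Hz)"
            )

    v = np.zeros((x.size, t.size))
    xs = x[:, None]
    for f, amp, phi0 in tones:
        omega = 2.0 * np.pi * f
        k = wavenumber(medium, omega)
        envelope = amp * np.exp(k.imag * xs)  # Im k <= 0: decay with distance
        if cylindrical_spreading:
            x0 = max(x[0], x[1] - x[0])
            envelope = envelope * np.sqrt(x0 / np.maximum(x, x0))[:, None]
        v += envelope * np.cos(omega * t[None, :] - k.real * xs + phi0)

    if noise_snr_db is not None:
        rng = np.random.default_rng(seed)
        sigma = np.max(np.abs(v)) * 10.0 ** (-noise_snr_db / 20.0)
        v = v + rng.normal(0.0, sigma, size=v.shape)
    return WaveField(x=x, t=t, v=v)


def wavefield_to_displacement(field: WaveField) -> np.ndarray:
    """Cumulative axial displacement (m) implied by a particle-velocity field.

    Returns shape ``(len(x), len(t))``; frame ``n`` holds the displacement
    accumulated up to ``t[n]`` (zero at the first frame), i.e. the running
    sum of ``v * dt``, matching a pre-push reference frame convention.
    """
    dt = field.dt
    d = np.concatenate(
        [np.zeros((field.v.shape[0], 1)), np.cumsum(field.v[:, :-1], axis=1) * dt],
        axis=1,
    )
    return d


@dataclass(frozen=True)
class IQProbe:
    """Tracking-probe parameters for the IQ generator.

    ``fc``: track transmit frequency (Hz); ``fs``: axial sampling frequency
    (Hz), default 2*fc which corresponds to quarter-wavelength sample
    spacing; ``pri``: pulse repetition interval (s); ``c0``: assumed sound
    speed (m/s); ``frac_bandwidth``: Gaussian pulse fractional bandwidth.
    """

    fc: float = 7.81e6
    fs: Optional[float] = None
    pri: float = 100e-6
    c0: float = 1540.0
    frac_bandwidth: float = 0.6

    @property
    def fs_(self) -> float:
        return self.fs if self.fs is not None else 2.0 * self.fc


def simulate_iq(
    displacement: np.ndarray,
    depth: np.ndarray,
    probe: IQProbe = IQProbe(),
    x: Optional[np.ndarray] = None,
    scatterer_density: float = 8000.0,
    snr_db: Optional[float] = None,
    seed: int = 0,
) -> IQSequence:
    """Render IQ tracking frames of scatterers following a displacement field.

    ``displacement``: axial displacement per frame, shape (depth, lateral,
    frame), m, positive away from the transducer.  ``depth``: the depth grid
    (m) on which the displacement is defined; the output IQ depth grid is
    resampled to the probe's axial sampling (spacing ``c0/(2 fs)``) spanning
    the same interval.

    Each lateral line holds its own random scatterers (positions uniform,
    amplitudes standard normal, ``scatterer_density`` per metre of depth).
    A frame is the sum of Gaussian-envelope echoes centred at the displaced
    scatterer depths, demodulated at ``fc``: a scatterer at depth ``z_s``
    displaced by ``d`` contributes

        a_s * exp(-(z - z_s - d)^2 / (2 sigma_z^2)) * exp(-i 4 pi fc (z_s + d) / c0)

    so the inter-frame IQ phase shift at fixed depth is ``-4 pi fc dd / c0``.
    Complex white noise is added at ``snr_db`` relative to peak |IQ|.
    """
    displacement = np.asarray(displacement, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if displacement.ndim != 3:
        raise ConfigError("displacement must be (depth, lateral, frame)")
    if displacement.shape[0] != depth.size:
        raise ConfigError("displacement depth axis must match the depth grid")
    n_lat, n_frames = displacement.shape[1], displacement.shape[2]
    if n_frames < 2:
        raise ConfigError("need at least 2 frames")

    fs = probe.fs_
    dz = probe.c0 / (2.0 * fs)
    z = np.arange(depth[0], depth[-1] + 0.5 * dz, dz)

    # Gaussian pulse: fractional bandwidth (FWHM of the spectrum) at fc.
    sigma_f = probe.frac_bandwidth * probe.fc / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_z = probe.c0 / (2.0 * 2.0 * np.pi * sigma_f)

    rng = np.random.default_rng(seed)
    span = depth[-1] - depth[0] + 8.0 * sigma_z
    n_scat = max(int(round(scatterer_density * span)), 8)

    iq = np.empty((z.size, n_lat, n_frames), dtype=complex)
    four_pi_fc_c0 = 4.0 * np.pi * probe.fc / probe.c0
    for j in range(n_lat):
        zs = rng.uniform(depth[0] - 4.0 * sigma_z, depth[-1] + 4.0 * sigma_z, n_scat)
        amps = rng.normal(0.0, 1.0, n_scat)
        for n in range(n_frames):
            ds = np.interp(zs, depth, displacement[:, j, n])
            zsn = zs + ds
            env = np.exp(-((z[:, None] - zsn[None, :]) ** 2) / (2.0 * sigma_z**2))
            phase = np.exp(-1j * four_pi_fc_c0 * zsn)
            iq[:, j, n] = env @ (amps * phase)

    if snr_db is not None:
        sigma = np.max(np.abs(iq)) * 10.0 ** (-snr_db / 20.0)
        noise = rng.normal(0.0, sigma / np.sqrt(2.0), size=(2,) + iq.shape)
        iq = iq + noise[0] + 1j * noise[1]

    return IQSequence(iq=iq, fc=probe.fc, fs=fs, pri=probe.pri, c0=probe.c0, x=x)


def burst_waveform(
    t: np.ndarray, f_exc: float, n_cycles: float = 1.0, window: str = "rect"
) -> np.ndarray:
    """Sinusoidal burst starting at t=0: ``sin(2 pi f t)`` over ``n_cycles``.

    ``window="rect"`` keeps the ideal sinusoidal onset the time-of-flight
    back-corrections assume; ``window="hann"`` tapers the burst for
    robustness experiments (its first peak then shifts away from T/4).
    """
    t = np.asarray(t, dtype=float)
    dur = n_cycles / f_exc
    inside = (t >= 0.0) & (t < dur)
    out = np.zeros_like(t)
    if window == "rect":
        w = 1.0
    elif window == "hann":
        w = np.sin(np.pi * t[inside] / dur) ** 2
    else:
        raise ConfigError(f"unknown burst window {window!r}")
    out[inside] = w * np.sin(2.0 * np.pi * f_exc * t[inside])
    return out


def simulate_twe(
    medium: Medium,
    f_exc: float,
    distance: float = 3e-3,
    internal_delay: float = 0.0,
    crosstalk_gain: float = 0.0,
    snr_db: Optional[float] = None,
    seed: int = 0,
    fs: float = 100e3,
    duration: float = 0.25,
    amplitude: float = 1.0,
    n_cycles: float = 1.0,
    window: str = "rect",
    n_averages: int = 1,
    crosstalk_path_fraction: float = 0.25,
) -> TWERecord:
    """Synthesize a torsional-wave record plus its air (crosstalk) reference.

    The air trace is the crosstalk alone, travelling a fixed fraction of the
    internal path: ``v_air = g * burst(t - gamma * internal_delay)``.  The
    specimen trace adds the wave propagated through the medium,

        v = v_air + A exp(-alpha(f) d) burst(t - internal_delay - d / c(f)) + noise,

    one noise realization per repetition (``n_averages`` rows).  Noise is
    white Gaussian at ``snr_db`` relative to the propagated burst's peak.
    """
    if not distance > 0:
        raise ConfigError("distance must be > 0")
    if not f_exc > 0:
        raise ConfigError("f_exc must be > 0")
    if internal_delay < 0:
        raise ConfigError("internal_delay must be >= 0")
    if fs <= 6.0 * f_exc:
        raise ConfigError("fs must exceed 6*f_exc to resolve the filtered burst")

    omega = 2.0 * np.pi * f_exc
    c = phase_velocity(medium, omega)
    alpha = attenuation(medium, omega)
    travel = distance / c
    arrival = internal_delay + travel
    if arrival + n_cycles / f_exc >= duration:
        raise ConfigError(
            f"arrival at {arrival:.4f} s plus burst exceeds the {duration} s record"
        )

    t = np.arange(int(round(duration * fs))) / fs
    v_air = crosstalk_gain * burst_waveform(
        t - crosstalk_path_fraction * internal_delay, f_exc, n_cycles, window
    )
    a_prop = amplitude * np.exp(-alpha * distance)
    propagated = a_prop * burst_waveform(t - arrival, f_exc, n_cycles, window)

    v_specimen = np.tile(v_air + propagated, (n_averages, 1))
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        sigma = a_prop * 10.0 ** (-snr_db / 20.0)
        v_specimen = v_specimen + rng.normal(0.0, sigma, size=v_specimen.shape)
    if n_averages == 1:
        v_specimen = v_specimen[0]

    return TWERecord(
        t=t,
        v_specimen=v_specimen,
        v_air=v_air,
        f_exc=f_exc,
        distance=distance,
        n_averages=n_averages,
    )
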