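# Methods

This note records the models the package implements, the numerical choices
behind them, what the synthetic generators do and do not emulate, and the
known limitations. Units are SI internally (Pa, Pa·s, kg/m³, rad/s, m/s);
kPa and Hz appear only at I/O boundaries.

## Viscoelastic wave model

A homogeneous, isotropic, linear viscoelastic medium of density ρ (default
1000 kg/m³, the usual soft-tissue assumption) carries plane shear waves with
complex wavenumber

    k(ω) = ω √(ρ / G*(ω)),     Re k > 0,

where G\*(ω) is the complex shear modulus of the chosen rheology:
Kelvin–Voigt G\* = μ + iωη, Maxwell G\* = iωμ₂μ₁/(μ₁ + iωμ₂), or the
elastic limit G\* = μ. Phase velocity and attenuation follow exactly:
c(ω) = ω/Re k, α(ω) = −Im k (Np/m). Because arg G\* ∈ [0, π/2] for all
three models, the principal complex square root automatically selects the
forward-decaying branch; no small-viscosity expansion is used. The common
Kelvin–Voigt closed-form approximation
c ≈ √(2(μ² + ω²η²) / (ρ(μ + √(μ² + ω²η²)))) is provided separately
(`kv_phase_velocity_approx`) for sensitivity checks only; the exact
evaluation is the default everywhere because it is unambiguous and testable
against closed-form limits (elastic: c = √(μ/ρ) at all ω; Maxwell high
frequency: c → √(μ₁/ρ), α → (μ₁/2μ₂)√(ρ/μ₁)).

## Synthetic data

The generators define the study conditions under which the chain is
validated; all are deterministic given a seed.

**Wavefield.** 1-D lateral plane-wave propagation: each source tone of
amplitude A at ω contributes A·e^(−α(ω)x)·cos(ωt − Re k(ω)·x + φ₀). There is
no diffraction or geometric spreading by default (a 1/√x cylindrical option
exists). The default source is a tone comb, 200–800 Hz every 50 Hz at
5 mm/s per tone: the integrated push displacement then peaks near 20 µm,
the scale a radiation-force impulse produces, and the record (20 ms at
PRI = 100 µs) places every tone on an exact DFT bin. Grids mimic a linear
array: 0.3 mm lateral pitch, up to 12 mm aperture.

**IQ tracking.** Per lateral line, random scatterers (uniform positions,
standard-normal amplitudes, 8000/m) are rendered as Gaussian-envelope
echoes (fractional bandwidth 0.6 at fc = 7.81 MHz) demodulated at fc, with
axial sample spacing c₀/(2fs), fs = 2fc (quarter-wavelength spacing). A
scatterer displaced by d carries the carrier phase −4π·fc·(z_s + d)/c₀, so
the inter-frame phase shift is −4π·fc·Δd/c₀. Complex white noise is added
relative to the peak |IQ|. The generator reproduces speckle (including
destructive-interference windows, which is what makes robust aggregation
necessary downstream) but not beam diffraction, element directivity, or
reverberation.

**Torsional-wave records.** The specimen trace is crosstalk + propagated
burst + noise: v = g·b(t − γτ) + A·e^(−α(f)d)·b(t − τ − d/c(f)) + n, with
internal delay τ, crosstalk path fraction γ = 0.25, emitter–receiver
distance d = 3 mm (the ring–disc radius; configurable because the
effective acoustic path of a real probe is not identical to the geometric
radius). The burst b is a one-cycle sinusoid with a rectangular window by
default: the arrival detectors back-correct by fractions of the period that
are exact for a sinusoidal onset, so the default burst must *have* a
sinusoidal onset; a Hann-tapered variant exists to probe robustness (its
first peak sits at T/3 rather than T/4, which biases uncalibrated
arrivals). Crosstalk is additive and specimen-independent, so air-reference
subtraction cancels it exactly by construction; noise (white Gaussian,
SNR in dB relative to the propagated burst's peak) is drawn per repetition
so averaging reduces it by √n. Fast-time sampling is 100 kHz and the
record 0.25 s by default (tests use 50 ms to keep runtimes short — the
burst and arrival occupy only the first few ms).

## Motion estimation

The Loupas 2-D autocorrelator estimates the inter-frame axial displacement
from the phase of the slow-time lag-one autocorrelation R₁ summed over an
M×N kernel (default 8 depth samples × 2 frames, centred and clipped at the
array edges so the output keeps the input depth grid):

    d = −(c₀ / 4π) · arg R₁ / f̂,     f̂ = fc + fs·arg(R_fast)/2π,

where R_fast is the fast-time lag-one autocorrelation over the same
window. Using the estimated local center frequency f̂ rather than the
nominal fc removes the bias of the plain Kasai estimator (available via
`method="kasai"`). Deviations |f̂ − fc| > fc/2 — far outside the 0.6·fc
echo bandwidth, i.e. destructive-speckle or noise-only windows — fall back
to fc. Estimates are signed (positive away from the transducer, depth
increasing downward), bounded by ±c₀/(4fc) per frame pair (quarter
wavelength round trip; larger shifts wrap), and reported per frame pair
(n−1 frames); cumulative maps relative to the first (pre-push) frame are
the default output. An optional coherence gate (normalized |R₁|) marks
meaningless windows as NaN.

Converting a map to a particle-velocity field divides the inter-frame
displacement by the PRI. By default the NaN-ignoring *median over the
depth rows* of the region of interest is taken rather than a single row:
speckle makes individual (depth, lateral) windows persistently unreliable,
and the plane-wave geometry makes depth rows redundant. A single row
remains available via `depth_index`.

## Dispersion extraction

Per lateral position, the slow-time record is Fourier transformed
(rectangular window, no padding by default — exact for on-bin sources;
Hann window and zero-padding are available and leave the phase slope
unchanged for isolated tones). The phase is unwrapped *along x* within each
frequency bin (the model φ = −Re k·x is linear in x), and Re k is the
negated ordinary-least-squares slope of φ(x) over the retained positions,
with the regression standard error propagated to the velocity spread.
Optional temporal smoothing of the velocity field is implemented as
circular convolution, so it multiplies every position's spectrum by one
common transfer function and provably cannot change the phase slope.

Filters, all of which *drop* rather than interpolate:

* bins whose peak amplitude is below 10 % of the spectrum's global peak
  (bands containing only noise come out empty);
* positions below 10 % of the bin's maximum amplitude (attenuated
  far-field);
* optionally, positions whose bin amplitude is below 3× their own noise
  floor, estimated as the median amplitude over an out-of-band interval
  (e.g. 900–2000 Hz when the source band is 200–800 Hz — above the band,
  everything is noise). This gate matters for *estimated* fields: at
  liver-like viscosity the wave at 500–800 Hz dies within a few mm, and
  unmasked noise-floor positions random-walk the unwrapped phase and bias
  the wavenumber high;
* bins with fewer than 3 usable positions or relative slope error above
  25 %.

Speeds use |Re k|, making the result invariant to the propagation
direction. An `x_range` can exclude the near-field push region.

## Time of flight

Per record: average repetitions, subtract the air reference, zero-phase
low-pass (forward–backward Butterworth, order 4, cutoff 3·f_exc — flat to
well under 0.1 dB at f_exc so arrival features do not shift). Detection:
(1) first crossing of 30 % of the global |trace| maximum (threshold applied
to the absolute value), (2) first positive peak after it, (3) next negative
peak. Back-corrections to the theoretical burst start: arcsin(0.3)/2π,
1/4 and 3/4 of the period — exact for a sinusoidal onset. The combined
arrival is the median of the three (robust to one outlier). Detectability
gate: the peak must exceed 5× the record's robust noise level
(1.4826·MAD of the whole compensated trace; the burst occupies a small
fraction of the record, so the MAD reflects the noise floor — a windowed
pre-arrival estimate fails at 200 Hz, where the burst period is comparable
to the arrival time). The internal delay is the least-squares constant
minimizing Σ(t_combined − d/c_ref − delay)² over records with known
reference speeds (e.g. an imaging-branch curve evaluated at each excitation
frequency) — with a single unknown this is the mean residual. Speeds are
d/(TOF − delay); repeated frequencies aggregate to mean ± SD.

## Rheological inversion

Weighted nonlinear least squares on *velocity* (the space in which
dispersion curves are drawn and their errors are roughly homoscedastic;
weights default to uniform, 1/σ² optional), trust-region reflective with
positivity bounds, five starts on a coarse log grid around the elastic
guess μ₀ = ρ·c̄². The elastic-informed initialization is deliberate: on
sparse, steep curves the positivity-constrained *global* optimum of the
Kelvin–Voigt objective can be a degenerate near-zero-elasticity solution
(the curve read as almost purely viscous), while the interior optimum
reached from the elastic guess is the physically meaningful one; the
four-point per-frequency-moduli refit in the test suite pins this behavior
against an independent optimizer. R² is computed unweighted on velocities
(defined as 1 for numerically perfect fits, covering degenerate flat
curves). Parameter 95 % intervals come from the Jacobian covariance
σ²(JᵀJ)⁻¹ with a t quantile; an ill-conditioned JᵀJ (> 10¹²), e.g. a flat
curve fit by the Maxwell model, flags the result.

Curve confidence bands are residual-bootstrap: residuals (inflated by
√(n/(n−p)) to restore the scale absorbed by the fit) are resampled onto
the fitted curve and the model refit from the optimum. The default band is
the symmetric t-based construction c_fit ± t₀.₉₇₅,ₙ₋ₚ·sd_boot, chosen over
the raw percentile envelope because at the 4–13 points a dispersion curve
typically has, the percentile band's truth coverage measured ~86–89 %
versus ~93 % for the t band at 95 % nominal; a percentile option remains.
Bootstrap refit failures are dropped, counted, and flag the band beyond
20 %.

Cross-technique agreement is the Pearson correlation of velocities paired
by nearest frequency within a tolerance (default 25 Hz, each point used at
most once); fewer than 3 pairs is treated as undefined.

On Kelvin–Voigt versus Maxwell selection by R²: both are two-parameter
families, and on weakly dispersive data (μ/ωη large over the band) both
reduce to near-flat curves, making the comparison a coin flip on noise.
Monte-Carlo at 2 % velocity noise over μ ∈ [0.5, 5] kPa, η ∈ [0.1, 1] Pa·s
gives Kelvin–Voigt win rates around 94 % — the Kelvin–Voigt model wins
essentially always when the data are meaningfully dispersive, and roughly
half the time when they are not.

## Problem sizes and determinism

Validation runs use desk-scale acquisitions: 24–41 lateral positions at
0.3 mm pitch, 200 frames at PRI 100 µs, 32-sample depth regions, 13-point
dispersion curves, 200-trial Monte-Carlo ensembles, 50 ms torsional
records. Every stochastic stage takes an explicit integer seed, and
pipeline reports embed a provenance block (config hash, seed, versions);
identical configurations reproduce byte-identical results.

## Limitations

* Isotropic, homogeneous, single-layer media only; no fractional-derivative
  or Zener rheologies.
* 1-D plane-wave lateral propagation: no diffraction, Mach-cone geometry,
  beamforming or element-level acoustics; speckle statistics are schematic.
* Axial (depth-direction) motion only; no RF-domain cross-correlation
  tracking.
* No attenuation-versus-distance fitting; attenuation enters only through
  the forward model.
* The torsional-branch crosstalk model is additive and specimen-independent
  by construction; real probes may exhibit load-dependent crosstalk that
  air-reference subtraction compensates only approximately (a mismatch
  factor is configurable for robustness studies).
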