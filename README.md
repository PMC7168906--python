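# swelast

Shear-wave and torsional-wave elastography post-processing: reconstruct
viscoelastic tissue biomarkers — shear wave speed, shear modulus μ and
viscosity η — from the dispersion of propagating shear waves.

Soft tissue is viscoelastic: its complex shear modulus G\*(ω) makes the
shear wave phase velocity frequency-dependent. Two measurement branches
produce the same currency, a dispersion curve c(f):

* **imaging branch (SWEI)** — an acoustic radiation force impulse pushes the
  tissue; the outgoing shear wave is tracked in complex IQ ultrasound frames.
  Axial motion is estimated with the Loupas 2-D autocorrelator, and the real
  wavenumber at each frequency comes from the phase gradient of the velocity
  field: for a plane wave, φ(x, ω) = −Re k(ω)·x, so c(ω) = ω / Re k(ω).
* **torsional branch (TWE)** — a rotating disc emits a shear burst that a
  ring sensor receives after crossing the specimen. After subtracting an
  air-reference record (crosstalk) and low-pass filtering at 3× the
  excitation frequency, the arrival time is detected three ways (30 %-of-max
  threshold, first peak, next negative peak), each back-corrected by its
  fraction of the period, and the speed is c = d / (TOF − delay), where the
  probe-internal delay is calibrated against known reference speeds.

Both curves feed a rheological inversion. With the exact complex wavenumber
k(ω) = ω·√(ρ/G\*(ω)) (root with Re k > 0, attenuation α = −Im k):

* Kelvin–Voigt: G\* = μ + iωη (speed grows without bound);
* Maxwell: G\* = iωμ₂μ₁ / (μ₁ + iωμ₂) (speed saturates at √(μ₁/ρ));
* elastic limit: μ = ρc².

Nonlinear least squares in velocity space returns the biomarkers with R²,
Jacobian-based parameter confidence intervals, and residual-bootstrap
confidence bands. A synthetic-data module stands in for the scanner and the
torsional probe, so the whole chain runs and validates end-to-end at desk
scale.

Intended users: researchers developing or validating elastography
post-processing who need a transparent, fully testable reference chain.

## Worked example

```python
import numpy as np
import swelast as sw

# liver-like Kelvin-Voigt medium: mu = 1.512 kPa, eta = 0.536 Pa.s
medium = sw.Medium(sw.KelvinVoigtParams(mu=1512.0, eta=0.536), rho=1000.0)

# synthesize a dispersive plane shear wave and extract its dispersion curve
x = np.arange(0.0, 12.001e-3, 0.3e-3)   # 41 lateral positions, 0.3 mm pitch
t = np.arange(0.0, 0.02, 100e-6)        # 200 frames at PRI = 100 us
field = sw.simulate_wavefield(medium, x, t, sw.tone_comb(200, 800, 50))
curve = sw.extract_dispersion(field, f_band=(200.0, 800.0))

fit = sw.fit_dispersion(curve, model="kelvin_voigt", rho=1000.0)
print(f"c(200 Hz) = {curve.c[0]:.3f} m/s, c(800 Hz) = {curve.c[-1]:.3f} m/s")
print(f"KV fit: mu = {fit.params.mu/1e3:.3f} kPa, eta = {fit.params.eta:.3f} Pa.s, "
      f"R^2 = {fit.r_squared:.4f}")
```

prints

```
c(200 Hz) = 1.315 m/s, c(800 Hz) = 2.037 m/s
KV fit: mu = 1.512 kPa, eta = 0.536 Pa.s, R^2 = 1.0000
```

The extracted curve rises from 1.32 to 2.04 m/s across 200–800 Hz — the
viscous signature — and the inversion returns the generating parameters
exactly on noiseless data. `sw.moduli_by_frequency(curve)` converts the same
curve to a per-frequency shear-modulus table in kPa (1.73 kPa at 200 Hz to
4.15 kPa at 800 Hz here).

## Command line

Each stage is also a subcommand (`swelast --help`):

```bash
swelast simulate iq  --config cfg.json --seed 2 --out iq.npz
swelast loupas       --kernel 8x2 --in iq.npz --out disp.npz
swelast dispersion   --band 200:800 --in disp.npz --out curve.csv
swelast fit          --model kv --rho 1000 --in curve.csv --out fit.json
swelast simulate twe --config twe.json --out records/
swelast tof          --delay 0.0008 --in records/twe_200hz.npz ... --out twe.csv
swelast run          --config pipeline.yaml --out report.json
```

Arrays travel as `.npz` containers with a JSON metadata block; dispersion
curves as CSV (`frequency_hz, velocity_m_s, velocity_std_m_s, n`); fits and
pipeline reports as JSON with kPa / Pa·s at the boundary.

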