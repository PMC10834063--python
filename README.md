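# memti

Reduced-order desk-scale simulator of **magnetoelectric (ME) core-shell
microdevices driven by magnetic temporal interference (MTI)**, with a
Hodgkin–Huxley analysis of the neural stimulation they can deliver.

## The problem

Wireless neural stimulation with remote coils faces a trade-off between
penetration depth and focality. One proposed escape is a battery-free
magnetoelectric microparticle: a magnetostrictive MetGlas sphere (100 μm
diameter) coated with a piezoelectric AlN shell (37.5 μm), placed between
two remote coils driven at *different* high frequencies f₁ and f₂ (126 and
188 MHz at 100 mA, 800 μm apart). The superposed fields beat at
Δf = |f₂ − f₁| = 62 MHz. A linear medium transmits that beat as a mere
envelope — no real spectral line at Δf exists, so nothing low-frequency is
delivered. The core's magnetostriction, however, is *quadratic* in the
magnetization,

    ε_me = (3/2)(λs/Ms²)·dev(M ⊗ M),     M = Ms·L(3χ₀|H_eff|/Ms)·Ĥ_eff,

(L is the Langevin function), so the particle itself demodulates the beat
into a genuine strain component at Δf. The piezoelectric shell converts
that strain into a surface electric potential (open circuit,
E = −(ε₀ε_T)⁻¹·d·σ), which drives an ohmic current through the adjacent
tissue. After low-pass filtering (100 MHz) and a 10⁶ time rescale that maps
62 MHz → 62 Hz, this current is a biologically plausible stimulus whose
effect on a neuron is assessed with the classical Hodgkin–Huxley membrane
model.

This package implements that full chain as a transparent, fast
reduced-order model: the core is a uniformly magnetized macro-spin with the
exact sphere demagnetizing factor N = 1/3 (replacing a finite-element field
solve), the shell is a thin perfectly bonded layer with geometric transfer
factor R/(R+t), and mechanical resonance enters through classical
free-sphere eigenmodes and an optional lumped resonator.

## What is in the box

| module | contents |
|---|---|
| `memti.materials` | MetGlas / AlN / geometry parameter sets, Voigt matrices, stiffness ↔ compliance |
| `memti.magnetostriction` | Langevin magnetization, deviatoric magnetostrain, self-consistent macro-spin state, DC bias sweep |
| `memti.mti_drive` | two-tone coil drive synthesis (Biot–Savart loop fields), air control, `Waveform` container |
| `memti.core_dynamics` | quasi-static nonlinear transduction, PSD estimation, difference-peak detection, optional resonator |
| `memti.eigenmodes` | torsional + spheroidal eigenfrequencies of the free elastic sphere, damping ratios, excitation-pair selection |
| `memti.piezo_coupling` | shell stress/field transfer, ME coupling coefficient α_ME = dE/dH in V/(m·Oe), bias/thickness sweeps |
| `memti.neuro_hh` | interface current, filtering, time rescaling, HH membrane, spike detection, amplitude/exposure sweeps |
| `memti.pipeline` / `memti.cli` | end-to-end orchestration, TOML config, provenance-hashed JSON/CSV reports |

## Worked example

```
$ memti demodulate --f1 126e6 --f2 188e6
difference peak at 62.04 MHz, prominence 28.1 dB, contrast PASS
```

The nonlinear core shows a spectral line at the difference frequency
(62 MHz, 28 dB above the local spectral floor with the default 20-beat
record); the identical drive passed through air shows none — that contrast
*is* the MTI demodulation effect.

```
$ memti bias-sweep
optimum bias 240.0 mT (window 110.0-300.0 mT), lambda_max 11.95 ppm

$ memti couple --bias-mT 293
alpha_ME = 57.74 V/(m*Oe) at 293 mT, shell 37.5 um

$ memti pipeline --out out/
pipeline complete: optimum bias 240 mT; pair 30.0/71.2 MHz; demodulation PASS;
alpha_ME 57.7 V/(m*Oe); min exposure 4.296875 ms
```

Reading the numbers: the magnetostriction curve saturates at the material's
12 ppm and is steepest around 240 mT — inside the 200–350 mT operating
window, consistent with the 293 mT operating bias carried in the default
configuration. The quasi-static ME coefficient is ≈58 V/(m·Oe); resonant
operation multiplies this by the mechanical quality factor (the lumped
resonator is exposed for that purpose). The pipeline's eigenmode stage also
reports its own lowest-loss excitation pair for the bare core
(30.0/71.2 MHz); the reference drive pair 126/188 MHz remains the drive
default. The stimulation stage sweeps the paper-range amplitude divisors
200–5000 over the filtered, time-rescaled chain current and finds that a
single action potential needs only ≈4.3 ms of exposure at the
stable-plateau amplitude.

Python API in one breath:

```python
import numpy as np
from memti.materials import load_default_metglas
from memti.mti_drive import DriveSpec, synthesize_drive
from memti.core_dynamics import transduce, power_spectrum, detect_difference_peak

core = load_default_metglas()
spec = DriveSpec()                      # 126/188 MHz, 293 mT bias
_, strain = transduce(synthesize_drive(spec), core)
s = power_spectrum(strain)
found, f, prom = detect_difference_peak(s, spec.f1, spec.f2)
print(found, f / 1e6, prom)             # True 62.04 28.1
```

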