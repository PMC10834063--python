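# Methods

This note documents the physical model behind `memti`, the parameters that
matter, the numerical choices, and the limits of what the reduced-order
results demonstrate.

## 1. Scope and philosophy

The device under study is a spherical magnetostrictive core (MetGlas
2628MB, 100 μm diameter) with a piezoelectric AlN shell (37.5 μm), placed
midway between two coaxial current loops that superpose a DC magnetic bias
and two sinusoidal tones at f₁ = 126 MHz and f₂ = 188 MHz. The package
replaces the 3-D finite-element multiphysics solve of that system with a
chain of well-characterized reduced models, each stage of which can be
verified independently:

1. **Drive** — on-axis Biot–Savart loop fields, scalar along the axis.
2. **Magnetics** — a single macro-spin with the exact sphere demagnetizing
   factor N = 1/3; anhysteretic Langevin magnetization.
3. **Magnetostriction** — deviatoric quadratic strain, saturating at λs.
4. **Elasticity** — classical free-sphere eigenmodes for frequency
   selection; an optional lumped resonator for resonant amplification.
5. **Piezoelectricity** — thin perfectly bonded shell, open-circuit
   strain-charge response.
6. **Neuron** — canonical squid-axon Hodgkin–Huxley membrane driven by the
   filtered, time-rescaled interface current.

The central fidelity reduction is spatial uniformity: one magnetization
vector and one strain scalar stand in for the full field distributions.
Everything the package claims quantitatively (difference-frequency
demodulation, saturation strain, stimulation breakpoints) survives this
reduction because it depends on the *constitutive nonlinearity*, not on
spatial structure. Everything that does not survive it is reported as a
property or a trend, never as an absolute number (§7).

## 2. Magnetic model

The applied axial flux density B(t) maps to the magnetization through the
self-consistent system

    H_int = H_applied − N·M,          N = 1/3 (sphere),
    H_eff = H_int + 3λs/(μ₀Ms²)·S·M   (stress feedback, S = external stress),
    M     = Ms·L(3χ₀|H_eff|/Ms)·Ĥ_eff,   L(x) = coth x − 1/x.

The Langevin argument is scaled by 3χ₀/Ms so that the zero-field slope
dM/dH equals the tabulated initial susceptibility χ₀ = 200 — the standard
anhysteretic parameterization; without it χ₀ would be unused. The λ₀
appearing in the stress-feedback term is read as the vacuum permeability
μ₀ on dimensional grounds. Remanence is zero by construction (anhysteretic
model); hysteresis and magnetocrystalline anisotropy are out of scope.

**Demagnetizing shear.** With χ₀ = 200 and N = 1/3 the *effective*
susceptibility seen from outside is χ₀/(1 + χ₀N) ≈ 2.96: the particle's
response is dominated by its own shape. A useful consequence: the knee of
the sheared magnetization curve sits at H_applied ≈ Ms/3, i.e. an applied
flux density μ₀Ms/3 ≈ 293 mT — the same field range where the
magnetostriction slope dλ/dB peaks (the default 201-point sweep puts the
argmax at 240 mT, window 110–300 mT). The 293 mT operating bias carried in
the default configuration is therefore physically natural for this
material, though it is treated as configuration, not as a model
prediction.

**Solver.** The axial case (the hot path: one solve per drive sample)
uses safeguarded Newton iteration on the monotone residual
g(M) = M − Ms·L(3χ₀(H − M/3)/Ms), whose derivative is ≥ 1; convergence is
quadratic and unconditional within the clipped bracket [−Ms, Ms]. The
general 3-vector case with stress feedback uses damped fixed-point
iteration with γ = 2/(2 + χ₀); plain undamped (or lightly damped)
iteration diverges because the fixed-point map has local slope ≈ −χ₀N ≈
−66. Tolerance 1e-10·Ms, diagnostic error with the last residual on
non-convergence.

## 3. Magnetostriction and the bias sweep

    ε_me = (3/2)(λs/Ms²)·dev(M ⊗ M)

is traceless, even in M (the key to frequency mixing), and gives parallel
strain λ∥ = λs(M/Ms)² for axial magnetization, saturating at
λs = 12 ppm. The bias sweep reports λ∥ against the **applied** flux
density μ₀H_applied (the coil-side quantity an experimenter controls);
the internal field differs by the demagnetizing term. dλ/dB uses central
differences; the optimum bias is the argmax on B > 0 with ties broken
toward smaller B, and the optimum window is the contiguous band with
slope ≥ 50% of the maximum.

## 4. Drive, demodulation, spectra

The two tones get equal amplitudes from the on-axis loop field
μ₀IR²/(2(R²+z²)^{3/2}) evaluated at the core center (z = 400 μm); with
I = 100 mA, R = 400 μm this is 55.5 μT per tone against a 293 mT bias.
The coil radius is not part of the reference geometry tables; 400 μm
(same order as the 800 μm separation) is the package default, and
`amplitude_override` decouples all demodulation results from this choice —
only the amplitude *ratio* matters for the contrast demonstrations.

Sampling defaults: 16 samples per f₂ period, 20 beat periods
(the reference study's own step, 0.1·0.05/f₂ ≈ 26.6 ps, is available as a
preset). Transduction is quasi-static — magnetization follows the field
sample-by-sample — because the demodulation mechanism is the static
quadratic nonlinearity; mechanical resonance only scales amplitudes, and
is available as a lumped second-order resonator
x¨ + (ω₀/Q)x˙ + ω₀²x = ω₀²λ(t) (default Q = 1/(2η) = 5000 from the 1e-4
loss factor), integrated as an exact zero-order-hold discrete LTI system
started from the DC bias steady state (the device is biased long before
the AC drive switches on; starting from zero would superpose a spurious
ring-down at ω₀ that can exceed the femto-strain difference line).

Spectra are one-sided Hann periodograms (mean removed, density scaling,
recorded Parseval ratio); nfft is the next power of two by default, or the
exact record length when coherent bins are wanted. The difference-peak
detector reports the maximum PSD bin within ±3 bins of Δf, refines the
frequency by parabolic interpolation on log power, and measures prominence
in dB over the local floor: the median PSD in a ±10% band around Δf,
excluding ±3 bins around each drive tone and harmonic (f₁, f₂, 2f₁, 2f₂,
f₁+f₂) and around the candidate peak itself. The detection threshold is
20 dB. With the default drive the core strain line sits at 62 MHz with
≈28 dB prominence; the air control (the same drive through a linear
medium) shows no line — only window leakage, a few dB above the floor.

## 5. Eigenmodes

Free vibrations of the homogeneous isotropic elastic core sphere
(E = 152 GPa, ν = 0.22, ρ = 7900 kg/m³ → c_s ≈ 2.81 km/s,
c_p ≈ 4.69 km/s). The characteristic equations are assembled directly
from the traction-free boundary conditions σ_rr = σ_rθ(φ) = 0 using
spherical Bessel functions and their derivatives:

* torsional: η·j_l′(η) − j_l(η) = 0, η = ωR/c_s (equivalently
  (l−1)j_l(η) = η·j_{l+1}(η));
* spheroidal: a 2×2 determinant in η and ξ = ωR/c_p; l = 0 reduces to
  x·j₀(x)/j₁(x) = 4c_s²/c_p².

The implementation was validated against the classical dimensionless
constants (first torsional l = 2 root η = 2.501; lowest spheroidal l = 2
root η = 2.640 at ν = 1/4) and against the independent l = 0 closed form.
Roots come from a dense linear scan (20 000 points per decade per branch
and angular order, l ≤ 6) with Brent polishing to ~1e-14; rigid-body zeros
are excluded by the scan window. Frequencies scale exactly as 1/R.

Damping: the uniform structural loss factor η = 1e-4 maps each real
eigenfrequency to f(1 + jη/2), so every damping ratio ζ = Im f/|f| sits at
the floor η/2 = 5e-5. Reported FEM damping ratios below 1e-15 are not
reproducible from a nonzero loss factor under this (or any first-order)
loss model; the package's ζ floor is η/2 by construction. The
excitation-pair selector picks, among modes with ζ ≤ ζ_max, the pair with
separation ≥ min_separation and lowest summed ζ (ties: lower f₁, then
lower f₂). For the bare 50 μm core it returns 30.0/71.2 MHz; the
reference pair 126/188 MHz — selected in the original study from the
*core-shell* mode structure, which is not analytically tractable — is
carried as the drive default.

## 6. Piezoelectric coupling

Perfect bonding transfers the core surface strain to the shell scaled by
R/(R + t) ≈ 0.571; the shell responds with its own stiffness
c_E = s_E⁻¹, and the open-circuit condition D = 0 (insulating shell, zero
volume charge) gives E = −(ε₀ε_T)⁻¹·d·σ. The AlN coupling matrix is
assembled in wurtzite 6mm symmetry (d₁₅ = d₂₄ = −3.8, d₃₁ = d₃₂ = −1.9,
d₃₃ = 5 pC/N); the two unlabeled shear compliances are assigned
s₄₄ = s₅₅ = 8, s₆₆ = 7.7 pPa⁻¹ (configurable, since the source tabulation
does not label them). The ME coefficient α_ME = |dE_z/dH|, converted with
1 Oe = 10³/4π A/m, is a two-point central difference of the full chain
(probe half-step 10 A/m). At 293 mT the quasi-static value is
57.7 V/(m·Oe); the chain-rule identity α_ME = |dM/dH·dλ/dM·dE/dλ| holds
to better than 1%, and the α_ME(bias) argmax coincides with the dλ/dB
peak by construction of the chain.

The surface potential between two electrode points is modeled as
V₀ = E_z·d_el with d_el = 3 μm (the electrode spacing of the reported
interface-impedance estimate). Thickness enters only through the transfer
factor, so α_ME decreases monotonically with t; the non-monotonic
37.5 μm optimum of the full FEM study is a resonant (mode-structure)
effect outside this model's scope.

## 7. Stimulation stage

**Interface.** i(t) = V₀(t)/(R_if·A), with R_if = 1 MΩ (endpoint of the
reported 0.45–1 MΩ range) and effective area A = 0.4 μm². A is the one
deliberate calibration knob in the package: the absolute scale of the
chain current is not identifiable from printed quantities (the original
study normalizes it away with amplitude divisors of 200–5000), so A is
chosen once such that those same divisors map the unscaled chain current
into the HH-relevant 0.5–20 μA/cm² band. All breakpoints below are
normalized to *peak current density* and are independent of this choice.
The mean of the current is removed: a capacitive piezoelectric source
sustains no DC through a resistive interface, and the reference waveform
is bipolar.

**Filtering and rescaling.** A 4th-order Butterworth low-pass at 100 MHz
is applied forward-backward (zero phase; 48 dB one octave above cutoff)
on the fast time axis, then the time axis is stretched by 10⁶
(62 MHz → 62 Hz, inside the 35–380 Hz band relevant for neural
stimulation). One beat period is trimmed from each record end to discard
filter edge transients. An important and deliberate consequence of the
printed filter spec: at 126 MHz the squared Butterworth response is still
≈0.14, so the dominant component of the stimulus is the *residual f₁
carrier* (126 Hz after rescaling), amplitude-modulated at the 62 Hz beat
by the weaker f₂ residual and the direct demodulated line. The neuron is
thus stimulated by a genuine temporal-interference waveform — carrier
plus envelope — not by a clean 62 Hz sine.

**Membrane.** Canonical squid-axon HH parameters (C_m = 1 μF/cm²,
ḡ_Na = 120, ḡ_K = 36, g_L = 0.3 mS/cm², V_Na = +50, V_K = −77,
V_L = −54.4 mV, standard α/β rate functions, rest ≈ −65 mV); the original
study cites the same classical source without printing rates. Integration
uses a fixed-step Rush–Larsen/midpoint scheme at dt = 10 μs: gates are
advanced with their exact exponential solution at the midpoint voltage
(unconditionally stable — an explicit RK scheme fails under strong
hyperpolarization, where the m-gate rate reaches ~2×10⁴/ms), the voltage
with an explicit midpoint update. Gates remain in [0, 1] through the
dynamics alone. Step halving moves spike times by < 0.1 ms. Spikes are
upward 0 mV crossings with a 2 ms refractory gap; a train is "regular"
when it has ≥ 3 spikes and ISI coefficient of variation < 0.1 (this
operationalizes "temporally consistent"; the original study does not
define it).

**Sweeps.** The amplitude sweep divides the stimulus by each scale and
shares one batched integration across all scales. The zero-spike
threshold is the largest grid amplitude with no spikes; the plateau onset
is the smallest amplitude of the largest amplitude-suffix with constant
spike count and all-regular trains; the minimum exposure bisects the
truncation time to 0.5 ms over a 200 ms simulation window.

With the reference configuration (1 s exposures, peak grid
0.5–20 μA/cm²) the package finds: zero spikes up to 2.75 μA/cm²,
1:1 envelope locking (62 spikes/s, CV < 0.1) from 5.0 μA/cm² upward, and
≈4.3 ms minimum exposure at the plateau amplitude. The threshold and
exposure agree with the reported ≈3 μA/cm² and ≤10 ms; the plateau onset
is lower than the reported 15 μA/cm² because it is controlled by the
*envelope modulation depth* of the beating carrier — here ≈9%, fixed by
the Butterworth residuals of the two tones — whereas the FEM chain's
resonant mode structure produces a much more deeply modulated waveform
that requires roughly 3× more peak current before every beat cycle
crosses threshold. This is a known, documented limit of the reduced
model, not a tunable.

## 8. What the synthetic drive does and does not emulate

The drive generator reproduces the deterministic structure the analysis
relies on — DC bias, two coherent tones of equal amplitude, and their
beat — and nothing else. It has no noise (the chain is noise-free and
seedless; repeated runs are bit-identical), no coil impedance or phase
drift, no off-axis field components, and no tissue attenuation.
Consequently the demodulation contrast demonstrated here is a clean-room
result: in real tissue the 20 dB prominence criterion would additionally
contend with measurement noise, and the air-control comparison would be
made against a noisy floor rather than a numerical leakage floor.

## 9. Pipeline, determinism, provenance

Stages run in the order bias sweep → eigenmodes → demodulation →
coupling → stimulation; any failure raises a structured error naming the
stage. The JSON report payload excludes timestamps and is bit-identical
across reruns of the same configuration; the configuration is hashed
(SHA-256 of its canonical JSON) into the provenance block. All stages are
deterministic; `random_seed` exists for noise-bearing extensions and the
white-noise spectral tests.

## 10. Known limitations

* Spatial field, strain, and surface-potential distributions ("hotspots")
  are outside the model; so are the absolute resonant α_ME (≈550
  V/(m·Oe) in the FEM study vs 57.7 quasi-static here), the 37.5 μm
  thickness optimum, and sub-1e-15 damping ratios.
* The shell is ignored in the eigenmode solve (bare core); mode
  frequencies are for frequency-selection methodology, not for matching
  the reference pair.
* The macro-spin internal field differs from the FEM's reported ≈66.7
  kA/m core average; the provenance of that number is unclear and it is
  not targeted.
* Thermal effects, SAR, hysteresis, and multi-particle interactions are
  out of scope.
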