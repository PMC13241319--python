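# convspec

Simulation and spectrum-recovery toolkit for **convolutional spectrometers**:
miniaturized spectrometers built from a cascade of unbalanced Mach–Zehnder
interferometers (MZIs) whose overlaid periodic transmittance is circularly
shifted along the wavenumber axis by proportional phase modulation.  The
shifting physically executes a circular convolution of the incident spectrum
with the system response, so the spectrum is recovered with nothing more than
a discrete Fourier transform and a bin-wise division — no compressive
sensing, no iterative solvers, and noise enters the result linearly.

The package is aimed at photonics and spectroscopy researchers who want to
explore cascade designs (FSR ratio ladders, stage counts, splitting ratios),
quantify achievable resolution and noise behaviour, and prototype the full
measurement → reconstruction pipeline on synthetic near-infrared spectra
before committing a design to fabrication.

## Model

An unbalanced MZI stage *i* with arm length difference ΔL_i, splitting ratio
ρ and effective index n_eff has transmittance

    r_i(ν) = ρ² + (1−ρ)² + 2ρ(1−ρ) cos(2π n_eff ν ΔL_i + φ_i),

periodic in wavenumber ν with free spectral range FSR_i = 1/(n_g ΔL_i).  A
cascade multiplies stage responses; its overlaid response repeats with the
composite FSR

    FSR_comp = LCM(FSR_1, …, FSR_n),

handled exactly through integer FSR ratios m_i = FSR_comp / FSR_i.  Driving
the stage phases with per-step increments Δφ_i = 2π m_i / N shifts the
overlaid waveform by exactly one grid sample per step over an N-point window.
The detector reading is then a circular cross-correlation,

    p[t] = δν Σ_ν x[ν] · r_sys[(ν − t) mod N],

so by the circular convolution theorem P[k] = δν · R_sys*[k] · X[k] and

    x̂[ν] = IDFT( P[k] / (δν R_sys*[k]) ),

with bins where |R_sys[k]| falls below a relative threshold zeroed
(pseudo-inverse on the known support) and an ideal low-pass at the response's
highest significant index k_max discarding noise-only bins.  The resolution
law is

    resolution = FSR_comp / k_max.

A product of n offset cosines reaches every frequency index |Σ ε_i m_i|
(ε_i ∈ {−1,0,1}); the ternary ladder m_i = 3^(i−1) covers 0…(3ⁿ−1)/2
contiguously, so resolution improves exponentially with stage count.

## Worked example

```bash
convspec design --stages 4 --fsr-comp 420 --out design.json
convspec respond --design design.json --out resp.csv
convspec fixtures --kind peaks --peaks "6350:25:1.0;6500:30:0.6" --out x.csv
convspec simulate --design design.json --spectrum x.csv \
    --noise-sigma 0.005 --seed 7 --out trace.csv
convspec recover --trace trace.csv --response resp.csv \
    --ref x.csv --out recovered.csv
```

prints

```
4-stage ternary cascade, ratios [1, 3, 9, 27], composite FSR 420 cm^-1, design resolution 10.5 cm^-1 -> design.json
k_max=40, resolution=10.5 cm^-1 -> resp.csv
fixture -> x.csv
trace (N=200, noise_sigma=0.005) -> trace.csv
k_used=40, suppressed_bins=119, epsilon=0.0288 -> recovered.csv
```

Reading: the 4-stage ternary cascade's response over one 420 cm⁻¹ window
(N = 200 samples, 2.1 cm⁻¹ step) carries contiguous frequency content up to
k_max = 40, i.e. a 10.5 cm⁻¹ resolution.  The simulated dual-peak spectrum,
measured with Gaussian noise at 0.5% of the maximum trace value, is recovered
with an L2-norm relative error ε ≈ 0.029 against the input; 119 DFT bins
outside the response's support were suppressed during the division.

The same flow is available as library calls (`design_cascade`,
`system_response`, `simulate_trace`, `recover_spectrum`, …); see the module
docstrings in `src/convspec/`.

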