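# Methods

This note records the model, the conventions that had to be fixed once, the
study conditions used by the test suite and benchmark battery, and the
limitations a user should know before trusting simulated numbers.

## Forward model

One measurement window is a uniform N-point wavenumber grid covering exactly
one composite FSR (half-open, samples ν_j = ν₀ + j·δν).  The overlaid
response of a cascade is the product of stage transmittances
r_i = ρ² + (1−ρ)² + 2ρ(1−ρ)cos(2π n_eff ν ΔL_i + φ_i); stage FSRs are
represented exactly as FSR_comp / m_i through integer ratios m_i
(gcd(m_i) = 1), so the composite-FSR LCM is integer arithmetic, never a
floating-point LCM.  Physical FSRs given as floats are rationalized by
continued fractions with denominators capped at 1000 (real ratio ladders are
small integers) and a relative tolerance of 1e-6; anything beyond that is
treated as incommensurable.

With a grid-aligned phase schedule (N steps per cycle, Δφ_i = 2π m_i/N) the
response shifts one grid sample per step, exactly.  The simulated detector
sequence is

    p[t] = δν Σ_j x[j] · r_sys[(j − t) mod N].

The (j − t) index direction is a fixed convention: it is the direction for
which DFT(p) = δν·conj(R_sys)·X holds for real sequences (numpy's forward
DFT, negative exponent, unnormalized; inverse carries 1/N), making recovery
a plain division.  Running the phase drive the other way measures the mirror
image of the spectrum; nothing physical distinguishes the two.  The δν
factor is the rectangle-rule quadrature weight of the underlying integral
and keeps recovered spectra in the input's units.

Noise is additive white Gaussian on p[t] with standard deviation
noise_sigma × max(p), from one seeded generator per trace.  This is a
declared stand-in — no detector noise statistics are modelled beyond it (no
shot noise, drift, or 1/f component).

## Recovery

x̂ = IDFT(P / (δν·conj(R))) with two safeguards:

* **Support suppression** (reg_tau, default 1e-3): bins with
  |R[k]| ≤ reg_tau·max|R| are zeroed rather than divided.  Hard zeroing is a
  pseudo-inverse on the calibrated support; for N ≤ 32 it matches an SVD
  pseudo-inverse of the full circulant system with the same relative cutoff
  (tested).  A Tikhonov-damped division is available but non-default.
* **Low-pass denoising** (default cutoff = the response's k_max at threshold
  tau = 1e-3): frequencies above the system's own support carry only noise.

The imaginary residue of the inverse DFT is discarded when below 1e-8
relative and flagged otherwise.  Recovered spectra are not clipped at zero
by default so the trace → spectrum map stays linear (clipping is an explicit
flag); as a consequence noisy recoveries carry small negative excursions.

The error metric is the L2-norm relative error
ε = ‖x_ref − x̂‖₂/‖x_ref‖₂.  Benchmark references are max-normalized by
construction, and recovery preserves scale, so ε is computed on raw values;
an explicit `normalize=True` re-normalizes both sides first.

## Dispersion and thermal drift

Group-index dispersion is modelled linearly, n(ν) = n_g0 + slope·(ν−anchor),
entering the phase as the warp ν → n(ν)·ν/n_g0 and stretching the FSR
periods.  Correction resamples the measured, stretched response onto the
uniform grid using a periodic cubic spline over the warped abscissae (cubic
rather than linear because the fastest stage of a 4-stage ternary cascade
has ~7 samples per period on the default grid, where linear interpolation
alone costs several percent RMS; the spline keeps the round-trip below 1%
for index changes up to 1% across the window).  Full recovery through a
dispersive system deconvolves on the warped coordinate and maps back with
the Jacobian dw/dν.

Thermal drift only shifts the waveform circularly; it is modelled as an
integer origin offset on the schedule and removed by re-registering the
trace against a calibration trace via the argmax of their circular
cross-correlation (scale-invariant; a flat correlation raises an
ambiguous-registration error).

## Study conditions and default device

* Default window: 6,250–6,670 cm⁻¹ (420 cm⁻¹ ≈ the 1,500–1,600 nm band),
  N = 200, δν = 2.1 cm⁻¹ — finer than half the system resolution, so the
  Nyquist condition k_max ≤ N/2 holds with margin.
* **Default device**: the ideal 4-stage ternary cascade (m = 1:3:9:27,
  ρ = 0.5), k_max = 40, resolution 10.5 cm⁻¹.  ρ = 0.5 maximizes modulation
  depth, and the ternary ladder is the coverage-optimal 4-stage design, so
  this is the best ideal 4-stage device; its mean transmittance is 1/16.
* **Flat-comb reference response** (`comb_response`): a tabulated synthetic
  response with uniform-amplitude components at k = 1…78 (Schroeder phases,
  minimal DC pedestal for nonnegativity, peak 1).  It emulates the rich
  contiguous frequency content a fabricated cascade exhibits once coupler
  imperfections and dispersion populate extra mixing products — content an
  ideal 4-stage product of cosines cannot reach (40 is its contiguous
  maximum).  The resolution benchmarks (5.4 cm⁻¹ law; dual-peak scans) run
  on it.
* Benchmarks: dual-peak scan uses equal 2 cm⁻¹-FWHM Gaussians, spacing
  stepped by 0.1 cm⁻¹ downward; a pair counts as resolved when the two
  largest separated local maxima have an inter-peak minimum ≤ 0.85× the
  lower maximum (an operational Rayleigh rule — the criterion itself names
  no threshold).  Dynamic range uses 8 cm⁻¹-FWHM peaks 210 cm⁻¹ apart,
  noise 0.5% of max(p), 50 seeds per amplitude; a peak is identified when a
  local maximum within 2 bins of its true position exceeds 5× the robust
  noise floor (1.4826·MAD of the recovery residual) in ≥90% of seeds.
  Broadband fidelity uses 10 fixtures (seeds 1–10), 5–10 Gaussian
  components of width σ ≥ 10 cm⁻¹, 0.5% noise, default recovery settings.

## Synthetic spectra

Gaussian peak sets (σ = FWHM/2.3548, max-normalized to the largest
amplitude, centers confined to the window so nothing wraps), random smooth
broadband waveforms (seeded sums of Gaussians, component σ drawn from
[smoothness, 3·smoothness], centers inset 2.5σ so truncation edges leak no
high frequencies — AC energy above k = 100 stays below 1% at the default
smoothness of 10 cm⁻¹), and gradually dipping/rising/shifting peak series.
What they do **not** emulate: source envelopes (SLD amplified spontaneous
emission), real reflectance/absorptance libraries, baseline drift, or
correlated detector noise.  Passing tests therefore demonstrate the
correctness and noise behaviour of the convolution/deconvolution machinery,
not end-to-end fidelity on real instruments.

## Known limitations

* **Dynamic range vs. broadband error under the stand-in noise model.**
  With noise fixed at 0.5% of the maximum trace value, small-peak
  detectability and broadband error pull the response design in opposite
  directions.  Detecting a 0.02-amplitude secondary peak needs near-uniform
  |R[k]| (low noise amplification per bin), but a nonnegative response with
  a flat comb needs a large DC pedestal, which inflates the trace maximum —
  and hence the injected noise — for broadband inputs (worst-batch ε ≈ 0.09
  on the flat-comb reference).  The cosine-product default device has the
  low mean transmittance that keeps broadband ε ≈ 0.04, but its high-order
  mixing components are weak, putting its measured detection floor near
  0.05 rather than 0.02.  Crest-factor bounds indicate no nonnegative
  response satisfies both under this noise convention; hardware achieves
  both when the physical noise-to-signal ratio is lower than the stand-in.
  The benchmark battery reports the honest value on the default device.
* Fractional (sub-grid) waveform shifts are out of scope: the exact circular
  convolution identity requires grid-aligned shifting.
* The dispersion model is linear in ν and shared by all stages; no
  per-stage or higher-order dispersion.
* Coverage enumeration is exact brute force over 3ⁿ sign patterns, intended
  for design exploration at realistic stage counts (n ≤ ~12).
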