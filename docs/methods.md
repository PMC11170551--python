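# Methods

## The attenuation model

One iteration of the band-selective pure-shift core element attenuates a
signal's integral by a product of independent factors:

- **Free relaxation.** A delay *t* with the magnetization longitudinal or
  transverse contributes exp(−t/T₁) or exp(−t/T₂).
- **Selective refocusing pulses.** Modelled as a biexponential decay
  exp(−α·t_p·(w₁/T₁ + w₂/T₂)) with a pulse-shape factor α and channel
  weights w₁ + w₂ = 1. The split between the two channels depends on pulse
  shape and trajectory detail that the closed form does not resolve; the
  symmetric default w₁ = w₂ = ½ is the neutral choice, and both weights are
  configurable. With one weight set to 1 the form reduces to free
  relaxation.
- **Diffusion.** A matched PFG pair flanking a 180° pulse attenuates by the
  Stejskal–Tanner factor exp(−D·γ²δ²g²Δ′). The corrected diffusion time Δ′
  is taken as user input rather than derived from sequence geometry,
  because the correction depends on gradient shape details outside this
  package's scope.
- **Convection.** Coherent plug flow along z gives cos(γδg·v_max·Δ) for a
  single iteration. Convection is *not* independent across iterations:
  with PFG polarity alternating between iterations the flow-induced phase
  cancels pairwise, so A_conv,n = 1 for even n and A_conv,1 for odd n.
  Consequently convection composes by parity, outside the f_elementⁿ law.
- **Imperfections.** A catch-all factor f_x ∈ (0, 1] per element.

Everything except convection obeys the exponent law
(f_element)ⁿ, which is what makes extrapolation in n work.

### J-modulation of chunked acquisition

Within each chunk of duration τ, J-evolution is refocused at the midpoint,
so the observed amplitude is modulated by ∏cos(πJ·u) with u ∈ [−τ/2, τ/2].
The centerband integral follows the *chunk-average* amplitude; expanding
each cosine to second order gives A_coupl = 1 − (π²τ²/24)·ΣJ². The
companion quadrature oracle evaluates the chunk average exactly (composite
Simpson, 4097 points; the integrand is smooth, and the quadrature error is
far below 1e−10 for realistic couplings), and the difference between the
two is O(τ⁴). The second-order form deliberately raises an error instead
of clamping when it goes non-positive — silently clamping would corrupt
downstream corrections; the exact oracle has no such restriction.

## The simulator

A weak-coupling analytic signal model: each active spin contributes
amplitude · exp(2πiνt) · ∏cos(πJt_J) · exp(−t/T₂), with t_J = t for
pulse-acquire and t_J the offset from the chunk midpoint for chunked
acquisition. The first chunk is a half-chunk [0, τ/2] so the first FID
point carries full amplitude; later chunks have midpoints at cτ. Chunking
sidebands at multiples of 1/τ then emerge from the periodic modulation
rather than being painted in. T₂ decay is applied as a continuous envelope
over assembled time, while relaxation during the iterated elements is
folded into the per-iteration factor — the two loss channels the method
distinguishes. Noise is complex circular Gaussian with mandatory seeds.
Frequencies are offsets from the carrier on a half-open axis [−SW/2, SW/2);
the FFT is scaled so the full-spectrum integral equals the first FID point,
making amplitude conservation exact on the discrete grid.

Interferogram and semi-realtime acquisition share this ideal signal model
(they differ in instrument bookkeeping, not in the noiseless signal), so
the simulator treats them identically apart from metadata.

Density-matrix propagation, strong coupling, Bloch–Siegert phase shifts and
spectrometer-instability artifacts are out of scope by design; the model is
exact precisely in the regime band-selective decoupling assumes (no mutual
coupling among active spins, weak coupling to passive ones), and the
simulator rejects systems that violate it.

## Quantitation

The default fit is ordinary least squares of ln I vs n ("semilog");
exponential nonlinear least squares (seeded by the semilog fit) is
available and agrees to first order in the noise. Iteration numbers need
not start at 1 nor be contiguous, supporting even-n-only designs under
severe convection. Per-point sigmas, when provided, weight the fits.
Integration regions default to five times the peak FWHM, wide enough to
include the weak ±J/2 relaxation sidebands that flank a decoupled
centerband. The J-modulation correction divides the fitted I₀ by A_coupl.
Compositions are proton-normalized mole fractions,
x_i = (I_i/p_i)/Σ(I_j/p_j).

Deviation reports follow the cross-experiment-mean convention: within each
replicate, each experiment's value is expressed as a percent deviation from
the mean over experiments; the report gives the mean over replicates with a
half-width of 1.96 × SEM. (The alternative normalization — relative
deviation in derived concentration — is a reporting variant, not
implemented as a separate code path.)

## Benchmark fixtures

**Water benchmark.** Four experiment sets with per-iteration factors
0.66, 0.55, 0.62, 0.51 applied as fⁿ (n = 1..3) to a common loss-free
integral, 13 replicates. The fixture operates at the integral level — the
quantity the pipeline consumes — with absolute Gaussian integral noise.
The default noise sigma (≈4.3×10⁻⁴ of I₀) is calibrated analytically by
the delta method so the base-experiment deviation half-width is ≈0.035%,
matching the reported uncertainty of the experimental benchmark. What this
fixture does *not* emulate: systematic deviations from exponential decay,
baseline/phase errors, and convection differences between experiments —
so passing it demonstrates the statistical behaviour of the extrapolation,
not robustness to systematic error.

**Three-component mixture.** Ibuprofen / diethyl ether / ethyl isovalerate
at 154 : 64 : 125 mM, one observed multiplet each, amplitudes proportional
to concentration × protons-per-signal. The multiplicities and J values of
the fixture are synthetic choices (plausible for the functional groups);
the experimental values for these specific signals are not published, so
the fixture supports pipeline tests and the printed mole fractions
(44.9 / 18.7 / 36.4%), not replication of the experimental deviation
tables.

## Monte Carlo planner

A Gaussian singlet (FWHM 1 Hz on a 0.05 Hz grid) is scaled by f_iterⁿ for
n = 1..5, per-point Gaussian noise is added, and the region integral over
5×FWHM is extrapolated by semilog fitting of n = 1..n_fit for
n_fit = 2..5, with 10 000 replicates per grid cell (1000 in fast mode).
SNR is peak amplitude over per-point noise sigma. The quantitation error is
2√2·σ_rel: σ_rel is the relative standard deviation of the extrapolated
integral, and the √2 accounts for comparing two such integrals. Because the
region integral of independent per-point noise is Gaussian with
σ·df·√m (m region points), the replicate loop draws integral noise directly
at that sigma; the explicit per-point path is retained and cross-checked in
the tests. Replicates whose integrals go non-positive are counted as fit
failures, never silently clamped. Noise draws are independent across
iterations within a replicate.

Default grids: f_iter ∈ {0.30, 0.35, …, 0.95},
SNR ∈ {50, 100, 200, 500, 1000, 2000}.

Without a time constraint, the optimal n_fit grows with f_iter (at low
f_iter the later, strongly attenuated points are too noisy to help; at high
f_iter extra points sharpen the slope estimate) and is essentially
independent of SNR. **Time normalization** compares n_fit options at equal
total experiment time by multiplying the error by √(time ratio). Two time
models are provided:

- `"transients"` (default): the iteration-i experiment costs its minimum
  phase-cycle length (2, 8, 16, 64, 128 transients for i = 1..5). In
  quantitative work each transient carries a long recovery delay (≥7·T₁),
  so total time tracks total transients; the steep growth of the required
  phase cycle makes n_fit = 2 optimal across the whole default grid.
- `"iterations"`: the iteration-i experiment costs time ∝ i
  (pre-acquisition duration only). This milder penalty leaves n_fit = 3
  marginally optimal at f_iter ≥ 0.9 (the error ratio between 3- and
  2-point fits approaches its homoscedastic limit ≈0.69·√2 ≈ 0.98 there).

The transient model is the default because the phase-cycle requirement is a
hard constraint of this pulse sequence, not an optional cost.

## Scheduling rules

Phase cycle: selective pulses cycle through (x, y) in odd iterations and
(x, y, −x, −y) in even ones; the full cycle is the Cartesian product,
2^⌈n/2⌉·4^⌊n/2⌋ transients, defined for n ≤ 5. Delay balance: each
iteration's J-refocusing element carries a (τ/4, τ/4) delay pair whose
J-evolution sense alternates between successive identical elements; for
even n the final pair is doubled to (τ/2, τ/2) so the net signed
J-evolution stays half a chunk (midpoint refocusing, absorption-mode
sidebands), and the adjustable padding delay of that iteration shrinks by
τ/2 so the total pre-acquisition time is exactly n × the single-iteration
duration (to 1e−12 s). The detailed layout beyond these rules (which delay
set is doubled, the default padding τ/2) is this package's reconstruction;
it is validated against the refocusing contract, not against instrument
code. No vendor pulse programs are generated.

## Known limitations

- Weak coupling only; no second-order (strong-coupling) spectra.
- The biexponential selective-pulse weights and the plug-flow convection
  cosine are approximations; both sit behind single functions so refined
  forms can be dropped in.
- The water benchmark's noise model is purely random; experimental
  deviations at the 0.1–0.3% level can include systematic components this
  model does not produce.
- SAPPHIRE-style sideband suppression, ultraselective excitation and raw
  spectrometer data ingestion are out of scope.
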