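# Methods

## Signal model

A single-voxel acquisition with a `C`-channel phased array, `A` repeated
samplings, and `N` complex points per FID is modeled as

```
X[c, a, n] = s_{c,a} · m(n) + q · E[c, a, n]
```

with coil sensitivities `s` (constant across averages unless a drift is
requested), the ideal voxel FID `m`, and zero-mean complex Gaussian noise
`E` that is independent across averages and time points but correlated
across coils with covariance `Ψ`. All combination methods are linear
estimators of `m`; their quality differs only in the weights.

## Conventions

- **ppm axis.** Spectra are stored with chemical shift decreasing along the
  bin index (conventional display orientation). `to_frequency` is the
  unnormalized DFT with bins reordered accordingly; `from_frequency` inverts
  it exactly. The ppm of frequency offset `f` Hz is
  `reference_ppm + f / f0[MHz]`; the reference defaults to water at 4.7 ppm
  (the protocol never fixes it, and 4.7 is the standard in vivo value).
  Region selection is by half-open ppm interval `[lo, hi)` over bin centers.
- **Complex Gaussian noise.** Real and imaginary parts are each standard
  normal, so a unit draw has total variance 2 per sample. No `1/√2` is
  applied anywhere; covariance estimates therefore carry this factor, which
  cancels in every whitening and weighting step.
- **Gauges.** Every combined FID is returned with its first time-domain
  point real and non-negative. All scoring is gauge-invariant (a complex
  least-squares scalar is fitted before comparison), so the choice only
  stabilizes tests and file outputs.

## Noise covariance

`Ψ̂ = ÊÊ^H / M` is estimated from the frequency-domain samples of a
noise-only window, 0.4–1.0 ppm by default. The `1/M` normalization keeps
the scale independent of the window width. Given a full block, one
covariance is estimated per average and averaged (a pooled estimate is an
option). The whitener is `W = D^{-1/2} G^H` from `Ψ̂ = G D G^H`; eigenvalues
below `1e-10·λ_max` are floored (and the model flagged rank-deficient) so
`W` always exists and is invertible.

Correlated noise is generated as `E_corr = L^H E_gauss` with `Ψ̂ = LL^H`
(Cholesky). Note the literal `L^H` coupling has population covariance
`∝ L^H L`, which differs from `Ψ̂` unless `Ψ̂` is diagonal; `exact_cov=True`
uses `L` and reproduces `Ψ̂` exactly. The literal form is the default
because every pipeline stage re-estimates `Ψ̂` from the data it whitens, so
the two are interchangeable end to end; tests that compare against a target
covariance use the exact form. Noise at level `q` is `q` times a unit draw;
the per-average generator is seeded from the pair `(seed, average_index)`,
making the level dependence exactly affine under a fixed seed.

## Combination methods

- **Brown.** Literal first-point weighting `m̂ = Σ_c X_c(1)·x_c` by default.
  Because the weight is not conjugated, per-coil phases add rather than
  cancel; the `conjugate_weights` option applies `conj(X_c(1))`, which makes
  the method exact on noiseless rank-1 data. The literal form is kept as
  the default deliberately — it is the published rule.
- **GLS.** `m̂ = (s^H Ψ̂⁻¹ s)⁻¹ s^H Ψ̂⁻¹ X`, implemented through the whitener
  for numerical symmetry. The sensitivity vector is read from the NAA
  resonance: for each coil, the spectrum value at the magnitude-maximizing
  bin (shared across coils) within 2.0 ± 0.15 ppm.
- **SVD / WSVD.** The leading singular triplet of the (whitened) coil
  matrix: `m̂ = Σ₁₁ v₁^H`, `ŝ = u₁`. Un-whitening applies to the
  sensitivity (`W⁻¹u₁`) and not to the length-`N` spectrum — a `C×C` matrix
  cannot act on the spectrum when `C ≠ N`, and the spectrum's scale/phase
  is a free gauge regardless. A tie between the top two singular values
  (1e-12 relative) is flagged and resolved by the deterministic LAPACK
  ordering.
- **ASSVD.** Four steps on the full block:
  1. *Pre-combination.* Each average is combined by WSVD. The per-average
     gauges are independent, so each `m̂_a` is aligned (complex least-squares
     scalar) to the WSVD result of the across-average mean. Aligning to a
     high-SNR reference rather than to the first average keeps the field
     coherent when single averages are noisy.
  2. *Pointwise sensitivities.*
     `s_{c,a}(n) = x_{c,a}(n)·conj(m̂_a(n)) / max(|m̂_a(n)|², ε)` with
     `ε = 1e-9·max|m̂_a|²`. The clipped denominator is exact (bias-free)
     wherever `|m̂_a|` is above the floor, which is what makes noiseless
     recovery exact to machine precision; a Tikhonov denominator
     (`|m̂|² + ε`) distorts the envelope near zero crossings of `m̂`.
  3. *Smoothing.* Each coil's `A×N` plane is convolved with a `k×k` uniform
     kernel (`k` odd, default 7), replicate-padded so constants pass
     through unchanged. `k=1` is the identity.
  4. *Re-combination.* Per `(a, n)`, one-unknown whitened least squares:
     `m̃(a,n) = Σ_c conj(s̃'_{c,a}(n)) x'_{c,a}(n) / Σ_c |s̃'_{c,a}(n)|²`
     (primes = whitened coil vectors), exactly the block solve of the
     stacked model since no two points couple. Points whose smoothed
     sensitivity vanishes (relative 1e-12) fall back to uniform unit
     weights and are counted in the result's parameters. The output is the
     arithmetic mean of the per-average solutions — the same reduction the
     comparators' input uses; the alignment in step 1 makes the average
     coherent.

  Sensitivity estimation and the solve run in the time domain by default
  (the domain of the acquisition model); a frequency-domain mode exists.

## Synthetic data

Metabolite spectra are sums of damped complex exponentials (Lorentzian
lines). Default decay rate 15 s⁻¹ (≈4.8 Hz FWHM, a typical 3 T singlet);
broader 22–25 s⁻¹ for the multiplet stand-ins (mI, Glu/Gln). Two presets:

- `invivo`: NAA 2.01 ppm dominant; Cr 3.03/3.91; Cho 3.19; mI 3.56;
  a Glu/Gln pair at 2.25/2.35; Lac doublet 1.28/1.34.
- `phantom`: amplitudes in the quality-assurance phantom concentration
  ratios NAA 12.5 : Cr 10 : Cho 3 : mI 7.5 : Glu+Gln 12.5 : Lac 5.

Amplitudes are expressed in units of the unit-level (1×) noise standard
deviation. The scale is calibrated once so that a whitened-SVD-combined
spectrum at 1× noise scores ≈45 dB for the phantom preset and ≈40 dB for
the in vivo preset with the reduced 8×16×512 geometry — the SNR levels
typical of 3 T single-voxel acquisitions of each kind.

Coil sensitivities have lognormal magnitudes (shape 0.5), uniform phases,
RMS magnitude 1, and are constant across averages — exactly the stability
assumption ASSVD rests on. An optional sinusoidal drift across the
averages dimension (one cycle, random per-coil phase) stresses that
assumption. Inter-coil noise coupling uses `(1-ρ)I + ρ hh^H` with
unit-modulus random `h`: unit diagonal, off-diagonal magnitude exactly
`ρ` (default 0.3), always positive semidefinite. Water is assumed
perfectly suppressed; no macromolecule baseline, eddy currents, or
frequency drift are simulated.

## Evaluation

`SNR = max(Re(x - x_baseline))² / mean(Re(x - x_fitted)²)` on the displayed
0.2–4.0 ppm window, reported as `10·log₁₀` (the numerator is already a
power). On synthetic data the fit is the ground-truth clean spectrum scaled
by one complex least-squares factor and the baseline is zero; externally
produced baseline/fit vectors can be scored through the same function. The
one-sided paired t-test uses `t = mean(d)/(sd(d)/√n)`, `df = n-1`, sample
standard deviation, upper-tail p; zero-variance differences are an error
rather than a convention.

Benchmark designs: the noise-level sweep runs all four methods at
`q = 1…7` (phantom preset), re-using the same unit noise field per
replicate so the level contrast is exactly paired; the kernel-size study
runs WSVD and ASSVD at `k ∈ {3,5,7,9}` on identical replicates (in vivo
preset, `q = 2`) with one-sided paired t contrasts per kernel. Default
problem sizes are the reduced geometry (8 coils, 16 averages, 512 points,
50 and 20 replicates), chosen so the full suite runs in seconds; the
full-scale 32×128×2048 geometry is available through the same
configuration object.

## What the synthetic benchmarks can and cannot show

Under this generator the model is *exact*: sensitivities are constant,
noise is stationary with the estimated covariance. In that regime the
whitened-SVD combination of the across-average mean is already at the
best-linear-unbiased bound — substituting the true sensitivities into
ASSVD's final solve reproduces WSVD's SNR to within a few hundredths of a
dB. Any estimated pointwise sensitivity therefore can only add noise: the
ratio `x/m̂` carries per-point errors that the `k×k` smoothing reduces by
only ~`k²` samples' worth, and the surviving weight fluctuations multiply
the *signal*, producing a distortion floor that keeps ASSVD below WSVD on
ideal synthetic data at every noise level. This is a property of the ideal
simulation, not a defect of the estimator: the pointwise, locally smoothed
weights are an adaptivity mechanism, and adaptivity is pure cost when
there is nothing to adapt to. On real repeatedly sampled acquisitions the
stability assumption is only approximate (scanner drift, motion,
shot-to-shot phase), which is where per-average pre-combination and
smoothing can pay off; reproducing that regime would require modeling the
very instabilities this simulator deliberately excludes. The benchmark
harness reports the measured ordering either way.

## Numerical choices

- Eigenvalue floor `1e-10·λ_max` for whitening; flagged, never silent.
- Sensitivity-division clip `ε = 1e-9·max|m̂_a|²`; degenerate per-point
  solves (relative denominator ≤ 1e-12) fall back to uniform weights.
- SVD ties flagged at 1e-12 relative; gauge by first-FID-point phase.
- All randomness flows through seeded `numpy.random.Generator`s; per-average
  streams derive from `(seed, average)` seed sequences.
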