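# mrscombine

Coil combination for multichannel, repeatedly sampled single-voxel magnetic
resonance spectroscopy (MRS), with a fully controlled synthetic-data
generator and an SNR benchmarking harness.

## The problem

A phased-array acquisition of one voxel yields a complex array
`X ∈ ℂ^{C×A×N}` of free induction decays: `C` receive coils, `A` repeated
samplings ("averages"), `N` time points. Each coil `c` records

```
X_c(n) = s_c · m(n) + E_c(n)
```

where `s_c` is the coil's complex sensitivity, `m` the ideal voxel signal,
and `E` thermal noise that is *correlated between coils* with covariance
`Ψ`. Merging the coils into one spectrum with the right weights is what
determines the SNR available for metabolite quantification. This package
implements four estimators of `m`:

- **Brown** — weight each coil by the first point of its FID,
  `m̂ = Σ_c X_c(1)·x_c` (a conjugate-weight variant is available);
- **GLS** — generalized least squares,
  `m̂ = (s^H Ψ̂⁻¹ s)⁻¹ s^H Ψ̂⁻¹ X`, with `s` read off the NAA peak at
  2.0 ppm;
- **WSVD** — whiten the coil dimension with `W = D^{-1/2}G^H` (from
  `Ψ̂ = G D G^H`), then take the leading singular component of `WX`;
- **ASSVD** — average-smoothing SVD: pre-combine every average with WSVD,
  estimate a pointwise sensitivity `s_{c,a}(n)` by regularized division,
  smooth each coil's `A×N` sensitivity plane with a `k×k` uniform kernel
  (default `k=7`), and re-solve for `m` point by point with whitened least
  squares. ASSVD is the only method that consumes the full `C×A×N` block
  rather than the across-average mean.

`Ψ̂ = ÊÊ^H/M` is estimated from a signal-free spectral window (0.4–1.0 ppm
by default). The same machinery generates correlated noise for simulation:
`E_corr = L^H E_gauss` with `Ψ̂ = LL^H`, scaled by integer levels
`q = 1…7`.

## Worked example

```python
import mrscombine as mc

meta = mc.reduced_meta()                      # 8 coils, 16 averages, 512 points
lines = mc.make_line_model("phantom")
psi = mc.make_correlated_psi(meta.n_coils, rho=0.3, rng_seed=0)
profile = mc.make_coil_profile(meta.n_coils, rng_seed=1)
block, truth = mc.simulate_block(lines, meta, profile, psi, q=2, rng_seed=1)

noise_model = mc.estimate_block_noise(block)  # from the 0.4-1.0 ppm window
xbar = mc.average_block(block)

spectra = {
    "brown": mc.combine_brown(xbar),
    "gls": mc.combine_gls(xbar, noise_model, mc.pick_naa_sensitivity(xbar, meta)),
    "wsvd": mc.combine_wsvd(xbar, noise_model),
    "assvd": mc.combine_assvd(block, noise_model, k=7),
}
for name, spec in spectra.items():
    report = mc.snr_synthetic(spec, truth, meta)
    print(f"{name:>6}: SNR = {report.snr_db:5.1f} dB")
```

prints

```
 brown: SNR =  25.8 dB
   gls: SNR =  40.7 dB
  wsvd: SNR =  40.6 dB
 assvd: SNR =  32.8 dB
```

The SNR is the squared peak of the baseline-subtracted real spectrum over
the mean-square residual against the (least-squares-gauged) ground-truth
spectrum, on the displayed 0.2–4.0 ppm window, in dB. Phase-insensitive
literal Brown weighting scrambles the coil phases and loses ~15 dB; GLS and
WSVD sit at the best-linear-unbiased bound for this simulation; ASSVD pays
an estimation penalty for its pointwise sensitivities here because the
simulated sensitivities are perfectly stable — see `docs/methods.md` for
why this is the expected behavior on ideal synthetic data and what the
method buys on real acquisitions.

## Command line

```
mrscombine simulate --preset phantom --coils 8 --averages 16 --points 512 \
    --rho 0.3 --level 2 --seed 1 --out block.h5 --truth truth.h5
mrscombine noise estimate --in block.h5 --out psi.h5
mrscombine combine --method assvd --in block.h5 --psi psi.h5 --kernel 7 --out spec.h5
mrscombine benchmark sweep --replicates 50 --seed 0 --out sweep.csv
mrscombine report --in sweep.csv
```

Every output carries a `.provenance.json` sidecar with the full parameter
set needed to regenerate it.

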