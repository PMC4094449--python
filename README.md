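# mreitaw

Conductivity-image enhancement for **magnetic resonance electrical
impedance tomography (MREIT)** with an adaptively weighted spatial
averaging filter, embedded in a complete desk-scale simulation pipeline.

## The problem

MREIT reconstructs the electrical conductivity σ(r) of tissue from the
z-component *B*z of the magnetic flux density induced by externally
injected currents, measured through the MR phase.  The noise of the
extracted flux density is position dependent:

    sd(Bz) = 1 / (2 γ Tc Υ),        Υ = M / s  (magnitude-image SNR),

with γ the proton gyromagnetic ratio, *T*c the current injection time,
*M* the MR magnitude and *s* its noise level.  Where the MR signal is
weak (short-T2 objects, lungs, gas pockets) the reconstructed
conductivity is swamped by noise while the rest of the image is fine —
so a uniform denoiser either leaves the noise or blurs the good regions.

## The method

The package filters the *reconstructed* conductivity image with a
per-pixel convex average whose reach and sharpness follow the local
noise estimate derived from the magnitude image:

    D(r, s)  = |M(r) − M(s)| / h(r),      s ∈ B_r(η(r)),
    w_r(s)   = e^(−D(r,s)) / ζ(r),        Σ_s w_r(s) = 1,
    σ_w(r)   = Σ_s w_r(s) σ(s),

with the distance denominator *h*(r) and the disc radius *η*(r) both
proportional to sd(*B*z(r)).  Quiet pixels (high SNR) get η = 0 and pass
through bit-exactly; noisy pixels are averaged over up to η_max = 6
pixels, but only against neighbors of similar magnitude, so boundaries
visible in *M* are preserved.

Everything around the filter is also implemented: a three-inclusion
disc phantom generator, a finite-volume Neumann solver for the injected
currents, a discrete Biot–Savart evaluation of *B*z, simulation of the
±current complex acquisitions with the phase-difference extraction, the
single-pass transversal J-substitution reconstruction, the ROI
gradient-variance quality metric

    V_D(σ) = ( 1/|D| ∫_D |∇σ|² dr )^(1/2),

and a reaction-diffusion (curvature flow + fidelity) baseline denoiser
for comparison.

## Worked example

```sh
cat > phantom.yaml <<EOF
acquisition:
  tc_ms: 2.0
EOF
mreitaw pipeline --config phantom.yaml --outdir run1 --seed 1 --no-baseline
```

prints the variance report of the default experiment (128×128, 240 mm
FOV, 0.4 S/m disc with 1.5 / 0.1 / 1.5-wrapped-in-0.3 S/m inclusions,
background SNR ≈ 30 vs ≈ 4 inside the short-T2 objects, two orthogonal
10 mA injections at *T*c = 2 ms):

```
	V_D1	V_D2	V_D3
Before filtering	641	755	748
After filtering	23.7	30.8	27
Reduction	96.3%	95.9%	96.4%
Mean reduction	96.2%
```

V (in S/m per m) is the RMS conductivity gradient inside each
homogeneous inclusion ROI — ideally zero, inflated here by the
flux-density noise of the weak-signal objects.  The filter removes ~96%
of it while the background and the region boundaries are left intact.
`run1/` contains every intermediate map (true and measured *B*z,
reconstruction, *h*/η maps, filtered image) as NIfTI-1 + CSV with a JSON
provenance record.

The same filter runs on real data from a pair of images:

```sh
mreitaw filter --sigma sigma.nii --magnitude magnitude.nii \
    --tc-ms 2.0 --noise-std 1.0 --out sigma_filtered.nii
```

From Python:

```python
from mreitaw.pipeline import default_config, run_phantom_experiment
res = run_phantom_experiment(seed=1, config=default_config(tc_ms=2.0))
print(res.report.to_text())
```

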