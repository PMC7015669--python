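# axonmap

Noninvasive mapping of effective axon radii from strongly diffusion-weighted
MRI.

## The problem

Axon caliber sets conduction velocity, and histology shows it changes in
disease — but axons are micron-sized while clinical diffusion MRI voxels are
millimeters, and the restricted-diffusion signal of a thin cylinder is
extremely weak (ln S ∝ −r⁴ for long gradient pulses). Two confounds have
historically wrecked dMRI axon-diameter estimates: extra-axonal water, and
fiber orientation dispersion. Both can be engineered away: powder
(spherical) averaging of the signal over many gradient directions at fixed b
factors out dispersion, and restricting the analysis to very high
diffusion weightings (b > 6 ms/μm² in vivo, b ≥ 20 ms/μm² ex vivo)
suppresses the fast-decaying extra-axonal compartment. What remains is the
orientationally averaged intra-axonal signal

S̄(b) ≃ β b^(−1/2) e^(−b·Da⊥) + f_im,  β = √(π/4) · f / √(Da∥),

a *truncated power law*: zero-radius "sticks" give the pure b^(−1/2)
scaling, a finite radial intra-axonal diffusivity Da⊥ > 0 truncates it, and
an immobile ("dot") water fraction f_im adds a plateau. Fitting this decay
and inverting the long-pulse (Neuman) cylinder response,

r_MR = ( (48/7) · δ(Δ − δ/3) · D₀ · Da⊥ )^(1/4),

yields the **effective MR radius** — the tail-weighted moment ratio
r_eff = (⟨r⁶⟩/⟨r²⟩)^(1/4) of the voxel's axon radius distribution, the one
scalar about that distribution that dMRI can measure. A hallmark of radius
sensitivity is a *negative* extrapolated intercept γ of the power-law fit
versus 1/√b; a convex decay in 1/√b instead signals inter-compartment water
exchange (the behavior of gray matter), modeled by the large-b Kärger
expansion S̄ = β(b^(−1/2) + c·b^(−3/2)) + f_im.

`axonmap` implements this pipeline for people who work with multi-shell,
ultra-high-b diffusion data (Connectom-class human scanners or preclinical
systems): Rician-maximum-likelihood spherical means via even-order spherical
harmonics, dot-fraction estimation and subtraction, fitting and AICc
ranking of eight candidate decay models, Da⊥ → r_MR conversion, Cramér–Rao
feasibility analysis of a protocol, histology radius statistics with
mesoscopic-fluctuation bootstraps, and a ground-truthed synthetic phantom
generator that makes every stage testable without scanner data.

## Worked example

Simulate a small Connectom-protocol phantom (δ/Δ = 13/30 ms, 13 shells with
b = 1…25 ms/μm², 60 directions each, SNR 52) whose axons all have effective
radius 2.5 μm, run the full pipeline, and compare with the truth:

```python
import numpy as np
from axonmap import preset, default_truth, end_to_end_recovery

proto = preset("connectom")
truth = default_truth(proto, shape=(4, 4, 1), radii=(2.5,), snr=52.0, seed=7)
rep = end_to_end_recovery(truth)
print(f"true r_eff = 2.5 um; median estimated r_MR = "
      f"{np.nanmedian(rep['r_hat']):.2f} um ({100*rep['median_rel_err']:+.1f}%)")
```

```
true r_eff = 2.5 um; median estimated r_MR = 2.42 um (-3.3%)
```

The estimate lands within a few percent; the residual deficit is mostly the
finite spherical-harmonic order of the powder average plus thermal noise.
Model selection on a noisy decay from the same ground truth shows why the
truncated power law (model vii) is preferred over the pure stick (vi), while
a free intercept (model ii) fits equally well *with a negative γ* — the
radius hallmark:

```python
from axonmap import SphericalMeanDecay, compare_models
bs = proto.b_values[proto.b_values > 6]
rng = np.random.default_rng(7)
beta, da = 0.3432, 7 * 2.5**4 / (48 * 2.4 * 13 * (30 - 13 / 3))
y = beta * np.exp(-bs * da) * bs**-0.5 + rng.normal(0, (1/52)/np.sqrt(60), bs.size)
print(compare_models(SphericalMeanDecay(bs, y, 0.0),
                     ("ii", "vi", "vii", "viii"), b_min=6.0).summary())
```

```
model    aicc  delta_aicc        rss  k  plausible    p_f_im  p_beta  p_Da_perp    p_c
   ii -123.24           0 2.5085e-05  2       True -0.017319 0.37273        NaN    NaN
  vii -123.04     0.20828 2.5613e-05  2       True       NaN 0.34347  0.0075925    NaN
 viii -120.61      2.6383 3.2659e-05  2       True       NaN 0.28051        NaN 1.2403
   vi -109.81      13.437 0.00013261  1       True       NaN 0.31128        NaN    NaN
```

Here ΔAICc ≥ 2 against both the stick (vi) and the exchange form (viii),
the fitted Da⊥ ≈ 7.6 × 10⁻³ μm²/ms maps back to r_MR ≈ 2.5 μm, and the
free intercept is negative (γ ≈ −0.017). Protocol feasibility for the same
scanner:

```python
from axonmap import minimal_detectable_radius
print(minimal_detectable_radius(proto, f=0.6, Da_par=2.4, fit_bmin=6.0).summary())
```

```
CRLB feasibility: f=0.6, Da_par=2.4, D0=2.4, fit b >= 6.0
minimal detectable radius r_min = 2.1 um
```

The same stages are scriptable from the shell
(`axonmap simulate | powder-average | fit | select-model | map-radius |
crlb | hist-stats | dotfrac`); see `axonmap --help`.

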