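# Methods

## Signal model and assumptions

The pipeline treats white-matter axons as long impermeable cylinders with
locally one-dimensional ("stick") diffusion plus a weak radial component.
For a pulsed-gradient spin echo with pulse duration δ and separation Δ
(b = g²δ²(Δ − δ/3), with g the Larmor-frequency gradient, γ_H fixed at
2.6752219 × 10⁻⁴ rad ms⁻¹ μm⁻¹ per mT/m), the radial attenuation of a
cylinder of radius r is the Gaussian-phase van Gelderen series over the
roots α_m of J₁′(α) = 0. In the long-pulse limit δ ≫ t_c = r²/D₀ this
collapses to ln S⊥ = −(7/48) g²δ r⁴ / D₀, which defines the bidirectional
map between the radial intra-axonal diffusivity Da⊥ and the radius. For an
axon radius distribution h(r) the signal is volume-weighted (∝ r²), so the
single scalar the measurement constrains is the tail-weighted effective
radius r_eff = (⟨r⁶⟩/⟨r²⟩)^{1/4} (in the narrow-pulse limit,
(⟨r⁴⟩/⟨r²⟩)^{1/2} instead; the square root keeps units of length, chosen
because the printed source formula's exponent was ambiguous).

Assumptions: powder averaging has removed orientation dispersion; the fit
range (b > 6 ms/μm² in vivo, b ≥ 20 ms/μm² ex vivo) has suppressed
extra-axonal water; exchange is negligible in white matter on the
experiment's time scale; almost all axons are in the long-pulse regime; and
the signal is normalized to S(b=0) = 1. No O(g⁴) corrections beyond the
Gaussian phase approximation are included, which bounds accuracy for large
radii.

## Candidate decay models and selection

Eight forms are fitted to (b, S̄) by unweighted nonlinear least squares:
power law with free exponent, fixed-exponent power law, truncated power
law, and exchange expansion — each with and without a free intercept.
Shells share a direction count, so the spherical-mean noise level is nearly
b-independent and unweighted least squares is appropriate. The intercept is
unconstrained by default (reported as γ; its sign is diagnostic), with an
optional constrained f_im ≥ 0 mode; Da⊥ is likewise unconstrained and a
negative estimate flags the voxel as biophysically implausible rather than
raising. Ranking uses the small-sample corrected Akaike criterion
AICc = n ln(rss/n) + 2k + 2k(k+1)/(n−k−1), with ΔAICc ≥ 2 read as a
significant preference. Simultaneous (f_im, Da⊥) estimation is exposed but
the landscape is degenerate; a dedicated dot measurement is the supported
path.

Optimization uses a deterministic multi-start grid (β from the data-implied
median of S̄√b at 0.5×/1×/2×; Da⊥ ∈ {0, 10⁻⁴, 10⁻³, 10⁻²} μm²/ms;
α ∈ {0.3, 0.5, 0.7}; c ∈ {0, 1, 5} ms/μm²) with a trust-region-reflective
solver at tight tolerances, so repeated runs are bit-identical.

## Spherical means and the Rician likelihood

Per shell, the spherical mean is the ℓ = 0 coefficient (over √(4π)) of a
real, orthonormal, even-order spherical-harmonic fit with lmax = 6 (28
coefficients), requiring ≥ 28 directions and falling back to lower order
with a warning otherwise. Coefficients are estimated by Rician maximum
likelihood with a pre-computed noise level σ (from a noise map or scalar
SNR — never estimated internally), initialized at the Gaussian
least-squares fit and iterated via the fixed point of the likelihood
equations (least squares against the Bessel-ratio pseudo-data
y·I₁/I₀(y·ν/σ²), exponentially scaled Bessels throughout).

One numerical subtlety is documented here because it shapes the estimator:
the Rician likelihood is even in each predicted amplitude, so if the stated
σ is inconsistent with the data (least-squares residuals ≫ σ — impossible
for an honest noise map, but easy to construct synthetically) the exact ML
solution folds signs in low-signal regions and drifts off the sphere mean.
The implementation therefore refines beyond least squares only when the
reduced χ² of the Gaussian fit is below 100; honest acquisitions measure
χ² of order 1–30 even for perfectly coherent fibers, and in the Gaussian
(high-SNR) limit the estimator coincides with ordinary least squares.

The dot fraction is estimated from repeated (N ≈ 60) high-b measurements
parallel to the mean fiber axis as the Rician-ML amplitude over S₀, clipped
to [0, 1] with an audit flag, and subtracted shell-wise
(S̄*(b) = S̄(b) − f̂_im); corrected values may legitimately go negative at
high b and are kept. ROI decays aggregate voxelwise means by the mean
(median available).

## Protocol presets and feasibility

Two acquisition presets are built in: a human Connectom-class session
(δ/Δ = 13/30 ms, shells b = 1, 3, 5, 7, 9, 11, 12.1, 13.5, 15, 16.9, 19.1,
21.7, 25 ms/μm², 60 directions each, SNR 52 at b=0, TE 62 ms) and an
ex vivo Aeon session (δ/Δ = 7.1/20 ms, 18 shells to 100 ms/μm², 60
directions, SNR 195, TE 30.4 ms). The Aeon shell positions are not
published; the default is uniform spacing from 2.5 to 100 ms/μm² and is
overridable.

Feasibility uses the Fisher information of the two-parameter truncated
power law (β, Da⊥) with f_im fixed at zero, over the shells in the fit
range, with Gaussian shell noise σ₀/√n_dirs (direction averaging makes the
shell mean near-Gaussian). The detection floor r_min is the smallest radius
on a 0.05 μm grid whose long-pulse Da⊥(r) exceeds 1.96 × the CRLB standard
deviation (one-parameter Wald criterion, p < 0.05). The nominal tissue
values behind the floor are explicit inputs, defaulting to f = 0.6 and
Da∥ = D₀ = 2.4 μm²/ms in vivo (0.8 μm²/ms is the suggested ex vivo value);
they are the analysis's only free assumptions and are reported alongside
the result. Under these defaults the Connectom floor computes to ≈ 2.1 μm
and the Aeon floor to ≈ 0.65 μm; the floor scales as the fourth root of
the noise level, so it is robust to moderate changes in the assumptions.
D₀ defaults to the estimated Da∥ as its proxy (Da∥ ≤ D₀, so radii carry a
small negative bias from this choice, damped by the fourth root).

## Synthetic phantom

The generator emulates the statistical structure the analysis assumes: a
Watson-dispersed intra-axonal compartment whose radial kernel is the
long-pulse e^{−b Da⊥} attenuation (Da⊥ from the radius map above), an
axially symmetric Gaussian extra-axonal compartment (present in the data
but never in the fitted models — its suppression at high b is exactly what
the fit range buys), an isotropic immobile fraction, and magnitude noise
formed as |S + n₁ + i n₂| with n ~ N(0, σ²), σ = 1/SNR, so the Rician
estimators face their true likelihood. The Watson orientation distribution
is integrated with a deterministic 300-node Fibonacci quadrature; shell
direction sets are Fibonacci lattices with a deterministic per-shell
rotation. Ground truth travels in a JSON sidecar next to the NIfTI/bval/
bvec/noise-map outputs.

Default geometry is a small voxel grid of homogeneous stripes spanning
radii 0.5–3 μm; the test and acceptance runs use 16–25-voxel phantoms,
chosen so the whole pipeline exercises in seconds while medians remain
stable. Dot-fraction scenarios use f_im = 0.13 at SNR 195 — the magnitude
and noise regime of fixed-tissue work (reported range 8–17%).

What the phantom does **not** emulate: time-dependent extra-axonal
diffusion, axonal undulation and caliber variation, cell bodies and glial
processes, anatomy, or acquisition artifacts (motion, eddy currents, Gibbs
ringing). Passing recovery tests therefore demonstrate correctness of the
estimation chain under the model's own assumptions, not robustness to
these real-data confounds.

## Numerical choices

- van Gelderen series: M = 20 roots by default with a convergence check on
  the last term (|term_M/Σ| ≤ 10⁻⁹ over both presets' parameter ranges);
  r = 0 short-circuits to ln S = 0. Bessel-derivative roots from scipy's
  bracketed solver; the identity 4 Σ 1/(α⁴(α²−1)) = 7/48 ties the series
  to the Neuman limit and is verified in the tests.
- Radius maps: negative Da⊥ propagates as NaN plus a flag map (implausible
  voxels are themselves a reported quantity), never an exception.
- Binned radius histograms use bin centers for moments, so a binned
  distribution and its expanded per-axon sample agree exactly.
- AICc floors rss at machine epsilon (with a warning) to keep the
  logarithm finite on perfect fits.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); fixed seeds give bit-identical phantoms and
  bootstrap draws.

## Known limitations

- The coherent-fiber limit (Watson κ → ∞) is the hardest case for the
  lmax = 6 powder average: the directional signal is maximally sharp and
  the truncation leaves a small (~5%) radius bias not present at realistic
  dispersions; recovered radii are statistically indistinguishable across
  finite concentrations.
- The exchange coefficient's proportionality constant (c = k_c·R·TE/De⊥)
  is not derivable from the decay alone; `residence_time` exposes k_c
  explicitly (default 1) rather than hard-coding it.
- Effective radii are tail statistics: patch bootstraps of heavy-tailed
  distributions show order-of-magnitude larger coefficients of variation
  for r_eff than for the mean radius, so single-patch histology comparisons
  are intrinsically noisy.
- Reconstructing the full h(r) from r_eff is ill-posed and out of scope.
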