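# Methods

## Model

The package reconstructs the isotropic complex shear modulus
G\* = |G\*|·e^{iφ} from time-harmonic shear-wave fields measured by MRE.
Assumptions inherited from the governing equation: linear viscoelasticity,
isotropy, and local homogeneity (the modulus is treated as constant across
the derivative stencil).  The displacement field **u** is decomposed per
drive frequency by a temporal DFT; the curl removes compression waves, and
every curl component at every frequency contributes one Helmholtz equation
per voxel.  The two MDEV estimators (see README) recover φ from the
*rotation* the Laplacian applies to the complex curl value and |G\*| from
the *length change*, pooled over all components m and frequencies n.

Estimator properties relied on throughout:

* zero-degree homogeneity — global field scale, the phase-to-displacement
  factor, and per-frequency amplitude differences cancel;
* φ̂ ∈ [0, π] by construction (clamped arccos);
* on noise-free data consistent with the model, the default pooled-cosine /
  through-origin forms and the alternative regression / ratio forms
  (selectable via `InversionConfig`) coincide exactly.

## Processing chain and conventions

1. **Unwrapping** — reliability-sorted (Herraez) unwrapping from
   scikit-image, per transverse slice by default (`volume3d` optional).
   Only the congruence contract is guaranteed (output ≡ input mod 2π);
   global per-slice offsets are irrelevant because the inversion uses
   spatial derivatives only.
2. **Smoothing** — 3×3×3 truncated Gaussian, σ = 0.65 voxels (a
   near-binomial 3-tap kernel), weights normalized to 1.
3. **Scaling** — optional multiplication by a radians-to-displacement
   factor; recorded in metadata, provably without effect on the maps.
4. **Temporal harmonic** — with the package-wide convention
   u(t) = Re[u\* e^{+iωt}] (`preprocess.TIME_SIGN`), the fundamental bin of
   the 8-sample DFT gives u\* = (2/T)·Σₜ sₜ e^{−2πit/T}.
5. **Curl** — second-order central differences on real and imaginary parts;
   voxels whose stencil touches the volume edge or a masked voxel are
   invalidated, never one-sided-differenced (keeps boundary artifacts out
   of regional statistics).
6. **Butterworth** — slice-wise 2D k-space filter with *amplitude* response
   H(k) = (1 + (k/k_c)^{2·order})^{−1/2}; the 100 m⁻¹ threshold is
   interpreted as the half-power radial cutoff (gain 2^{−1/2} there), since
   gain-at-cutoff conventions differ.  Order is unspecified in the
   standard processing; default 3, configurable.  No padding by default
   (plain periodic FFT); mirror padding behind a flag.  A 3D variant
   exists for experimentation.
7. **Inversion** — 2D in-plane 5-point Laplacian by default (matching the
   2D slice-wise filtering); 3D 7-point selectable.  ρ defaults to
   1000 kg/m³ (brain).  Voxels with pooled Σ|Δc| below 10⁻⁹ × its median
   are masked invalid: amplitude nulls are what multifrequency pooling
   mitigates, and residual nulls must not produce infinities.

Axis convention everywhere: `[frequency][component][timestep][z][y][x]`
internally, NIfTI `(x, y, z, t)` on disk, one file per (frequency,
component), JSON sidecar for metadata, NaN *plus* an explicit mask for
invalid voxels.

## The phantom simulator

`phantom_sim` generates the study conditions the reconstruction is tested
under: 2 mm isotropic voxels, up to 96×88×30 volumes, 3 motion-encoding
components, 8 samples per vibration cycle, drive frequencies 30/40/50/60 Hz,
Gaussian noise on the raw phase (default σ = 0.2 rad), and phase wrapping
into (−π, π].

* **Plane-wave fields** are exact homogeneous solutions with wavenumber
  k = ω√(ρ/G\*) on the principal branch (Re k > 0, Im k ≤ 0), so the wave
  *decays* along propagation under the e^{+iωt} convention; each source's
  propagation distance is referenced to its entry point into the volume.
  The branch lives in one named, unit-tested function because a sign error
  silently flips φ.
* **Source amplitudes** default to 30 µm per source (160 µm for noise
  studies, the largest value that keeps the per-voxel phase step below the
  unwrapping Nyquist limit at 5×10⁴ rad/m) and scale as (f/f_min)^{−2}
  across frequencies — constant drive acceleration, matching the
  observation that low-frequency components dominate in vivo.
* **Heterogeneous oracle** — a sparse 5-point finite-difference solve of
  ρω²u + ∇·(G\*∇u) = 0 on one slice with Dirichlet boundary drive, used
  for inclusion phantoms.

What the phantom does *not* emulate: skull-borne distributed excitation,
compression-to-shear mode conversion, scattering at sulci and interfaces,
physiological noise, and frequency dispersion of G\*.  Consequently a
corner-driven homogeneous box at φ = 0.9 has a shear decay length of only
~8–13 mm, so voxels far from a source are noise-dominated at *any* filter
setting — unlike brain parenchyma, which is insonified from everywhere.
Noise-behavior checks are therefore evaluated over the **well-insonified
core** (clean wave amplitude ≥ 50 % of its interior maximum), the
in-silico analogue of parenchyma with adequate wave penetration.  Passing
tests demonstrate the estimator mechanics under controlled conditions, not
end-to-end in vivo accuracy.

## Noise behavior of the estimators

Phase noise propagates through the curl (a first-difference operator) into
mid-band spatial frequencies whose discrete Laplacian is strongly
anti-correlated with the noise itself.  Two regimes follow:

* **moderate noise** (well-insonified voxels): the pooled denominator
  Σ|x||Δx| inflates faster than the numerator, so φ̂ rises above truth and
  |Ĝ\*| falls below it — the documented in vivo asymmetry.  Smoothing
  removes the Nyquist-band noise (which pulls φ̂ *down*) and thereby pushes
  φ̂ further up before the Butterworth filter brings it back toward truth;
  the simulated smoothed→filtered φ decrease (≈0.05) matches the scale
  reported for in vivo processing.
* **noise-dominated voxels**: both estimators converge to attractors set
  by the noise spectrum (|Ĝ\*| → ρω²h²-scale values, φ̂ → ≈0.3–0.5),
  which is why unfiltered elastograms collapse.

The region-level Helmholtz scatter (one point per frequency and component:
mean ρω²|c| against mean |Δc|) makes the mechanism visible: noise inflates
the abscissa, a through-origin fit underestimates |G\*|, an
offset-allowing fit restores the slope, and the abscissa intercept is
positive.

## Statistics

Regional means use the sample SD (n−1) for both regional and inter-subject
variation.  Group averages track per-voxel valid counts.  Regional
comparisons default to a **paired** two-tailed t-test at the 5 % level
(regional values come from the same subjects); an independent-samples
variant and a Bonferroni-corrected threshold are available but off by
default, matching the single-threshold convention.  A paired sample with
zero-variance nonzero differences is reported as degenerate (infinite t,
p = 0) rather than failing.

## Numerical choices and problem sizes

* Second-order stencils bias |Ĝ\*| by ≈(kh)²-scale factors: ≈1 % at
  12 voxels/wavelength for in-plane 45° propagation, the configuration
  used in recovery tests precisely because it minimizes the anisotropic
  part of the truncation error while keeping the full k² in the in-plane
  Laplacian.
* Test and acceptance phantoms use 48³-scale grids (seconds per
  reconstruction); the full-size in-silico subject (96×88×30 × 3 × 8 × 4,
  ≈24 M phase samples) runs end-to-end in well under a minute and is
  exercised once for the reproducibility check.
* Degenerate inputs fail loudly with the offending index named: all-NaN
  slices in unwrapping, missing (frequency, component) files, shape
  mismatches per axis, empty valid regions in the inversion, singular
  Helmholtz systems.

## Known limitations

Isotropic, mono-exponent-free (model-free) recovery only: no dispersion
fitting, no anisotropic or poroelastic inversion, no registration or
template building (aligned maps are assumed).  The 2D Laplacian default
underestimates |G\*| for strongly through-plane-propagating waves; use
`laplacian_mode="3d"` when the field is not predominantly in-plane.
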