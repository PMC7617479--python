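# Methods

## Model and assumptions

The package models the spherical-mean (powder-average) MRI signal of water
confined in a distribution of parallel-walled cylindrical pores as a
volume-weighted mixture over radii,

    S̄(b, TE) = k Σᵢ wᵢ · exp(−TE/T2i(rᵢ)) · S̄_Diff(b, rᵢ),
    wᵢ = cᵢ rᵢ² / Σⱼ cⱼ rⱼ²,

where cᵢ are multiplicities (1 for listed radii, bin counts for histogram
input). The r² weighting expresses that each cylinder contributes in
proportion to the water volume it holds.

Assumptions, in decreasing order of importance:

* **Only intra-pore water contributes.** The estimators assume the
  extra-pore signal is suppressed by the high diffusion weighting
  (b ≥ 5000 s/mm²); the simulator deliberately contains no extra-pore
  compartment so that the estimators are evaluated under their own model.
* **Circular cross-sections.** Radii are circular-equivalent, r = √(A/π).
* **No exchange** between pores or across walls, no distribution of
  intrinsic diffusivities or bulk T2 — a single D∥ and T2b describe the
  filling fluid.
* **Gaussian phase distribution.** The radial diffusivity D⊥(r) follows
  the van Gelderen series (zeros of J₁′, first m = 18 terms by default;
  truncation error < 10⁻⁶ relative against a 200-term evaluation over
  r ∈ [0.1, 10] μm at δ/Δ = 9/35 ms). The wide-pulse (Neuman) closed form
  D⊥ = 7r⁴/(48 D∥ δ(Δ−δ/3)) is implemented for comparison only: it is
  within 5% of the series for r ≤ 1 μm but off by >20% at r = 5 μm under
  the same timings. A separate medium-pulse approximation is declared but
  not implemented (its closed form is not available to this package); the
  van Gelderen series covers both regimes.

## Units

Radii in μm; times (δ, Δ, TE, T2) in ms; diffusivities in μm²/ms; b-values
accepted in s/mm² and converted internally (×10⁻³) to ms/μm²; gradient
amplitudes in mT/m; surface relaxivity ρ₂ in nm/ms (×10⁻³ inside the
Brownstein–Tarr relation so that 1/T2i = 1/T2b + 2ρ₂·10⁻³/r with r in μm).
The proton gyromagnetic ratio is fixed at 2.6752218744×10⁸ rad s⁻¹ T⁻¹.
Protocols carrying both G and b are validated for consistency through
b = γ²G²δ²(Δ−δ/3) at a 5% tolerance — the nominal acquisition values
(G = 166.8 mT/m, δ/Δ = 9/35 ms, b = 5000 s/mm²) are mutually consistent
only to ~3%.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| D∥ (intrinsic diffusivity) | 2.0 | μm²/ms | free water near room temperature; measured from a control tube in practice |
| m (series terms) | 18 | — | truncation error ≪ noise for the radii and timings of interest |
| T2b (bulk T2) | 3000 | ms | de-ionized water; estimated from a free-water control series by `estimate_t2b` |
| ρ₂ search interval | [0.1, 20] | nm/ms | generously brackets polymer-wall relaxivities (~2–5 nm/ms) |
| radius fit bounds | [0.05, 15] | μm | below the smallest detectable and above the largest simulated pore |
| SNR | 34 | — | acquisition noise level; σ = mean TE=51 ms b0 signal / SNR |

## Fitting

All fits minimize the mean squared residual with bounded L-BFGS-B. The
single-cylinder fits (scale, radius) normalize the series by its maximum
(making the fitted radius exactly invariant to rescaling — the scale
parameter absorbs the signal level), profile the scale at each start, and
use 10 multi-start initializations log-spaced in radius; loss ties break
toward the smaller radius. A fitted parameter within 1% (relative) of a
search bound sets `bounds_hit`; non-convergence is flagged, not raised.

The ρ₂ calibration matches a measured multi-TE series to the synthetic
volume-weighted relaxation series of the known radii. The scale is profiled
in closed form, so the search is one-dimensional: a 200-point coarse grid
over the ρ₂ interval, then bounded refinement between the neighbors of the
grid optimum (matches a Δρ₂ = 0.001 brute-force grid to < 0.01 nm/ms).

The SNR estimator divides voxelwise mean/SD ratios over b0 repeats by the
chi-distribution small-sample factor √(ν/2)Γ((ν−1)/2)/Γ(ν/2), ν = repeats−1
(≈1.253 for five repeats), so it estimates the underlying Gaussian SNR
rather than the upward-biased naive ratio.

## Synthetic phantoms

Five presets emulate co-electrospun hollow-microfiber specimens. Radii are
drawn from two-component truncated lognormal mixtures: a bulk component
(log-sd 0.30) holding 98.5% of the fibers and a minority tail component
near 2.5–3.4 μm (log-sd 0.40) supplying the large pores, truncated at
8–10 μm. The bulk log-means are solved so the mixture means equal the
SEM-reported per-phantom means (1.07, 1.07, 0.70, 1.18, 1.21 μm); the tail
weight was set (once) so the presets also reproduce the observed
near-identity between the moment ratio ⟨r²⟩/⟨r⟩ and the relaxation
effective radius — a heavier tail matches the means but not that
relationship, so it would misrepresent the specimens. Fiber counts per
preset match the SEM sample sizes (7246–11827). Four presets are parallel
bundles; one is two bundles crossing at 90° (the powder average is
verified invariant between the two at the 1% level). Ground-truth surface
relaxivities for simulation are {3.5, 3.9, 2.0, 4.3, 3.1} nm/ms: one
deliberately low outlier standing for a degraded material, the rest
spread about a mean of 3.7.

Gradient directions (48 per shell) are generated by antipodally symmetrized
electrostatic-repulsion optimization from a fixed seed; the equal-weight
powder average over this set tracks the analytic spherical mean to a few
tenths of a percent for all simulated shells. Rician noise (|S + n₁ + i·n₂|,
nᵢ ~ N(0, σ)) is applied independently per measurement with σ set by the
TE = 51 ms b0 signal over the target SNR.

What the simulator does *not* emulate: extra-pore water, exchange,
non-circular cross-sections, wall-thickness (myelin-like) compartments,
orientation dispersion within a bundle, spatial heterogeneity across
voxels (all voxels share one underlying signal), and scanner artifacts.
Passing tests therefore demonstrate internal consistency of the estimators
under their own assumptions — not accuracy on tissue.

## Numerical choices

* The spherical-mean closed form uses a guarded evaluation: when
  b(D∥−D⊥) < 10⁻¹² the erf(x)/x factor is replaced by its Taylor expansion
  1 − y/3 + y²/10, removing the 0/0 at the isotropic limit; at b = 0 the
  signal is exactly 1. Agreement with a 10⁴-point spherical quadrature is
  < 10⁻⁴ absolute over b ∈ [0, 10] ms/μm², D∥ ∈ [0.5, 3].
* D⊥ is clamped to [0, D∥].
* Bessel-derivative zeros are tabulated once (256 roots) at import.
* Degenerate inputs raise ValueError with specific messages (empty samples,
  nonpositive radii, non-increasing axes, T2i ≥ T2b inversion, zero-variance
  regression).

## Design choices on genuinely open points

* **No b0 normalization before fitting.** Dividing multi-TE spherical means
  by TE-matched b0 images would cancel the T2 decay being estimated; the
  free scale K (or β) absorbs the absolute signal level instead.
* **Acquisition-matched grids.** Synthetic distribution-level series are
  evaluated on the same six-TE / five-b grids as the measurements, since
  calibration compares the two curves point by point.
* **Voxel handling.** The pipeline fits the mean spherical-mean signal over
  the (masked) voxels of a specimen and carries the across-voxel SD as an
  error bar only; no voxelwise radii.
* **Raw magnitudes.** No Rician bias correction or denoising is applied;
  see limitations.
* **Regression.** Radius sets are compared by unweighted OLS with Pearson R
  and a two-sided t-distributed p-value (n−2 df), no multiple-testing
  correction.

## Known limitations

* **Magnitude (Rician) noise floor.** Directional signals near the fiber
  axis decay to essentially zero, so their magnitudes fold up to
  ≈ σ√(2/π), inflating the powder average with a b-dependent differential.
  At SNR 34 this floor is comparable to the radius-driven component of the
  multi-b decay: the diffusion-branch radius fitted to raw magnitude data
  is biased low (in the simulator's compartment-free setting it can
  collapse to the lower bound), and averaging more voxels does not remove
  the bias. The T2 branch is robust to the same floor because calibration
  and estimation share it — the calibrated ρ₂ shifts, but the estimated
  radius still matches the distribution-level reference (the regression
  slope across the five presets stays within a few per mil of 1). This is
  the package's main caveat for the diffusion branch on low-SNR data.
* **Quadrature sensitivity of the diffusion fit.** The 48-direction
  equal-weight powder average carries a ~0.3–0.4% error that the
  ill-conditioned radius fit amplifies to several percent; the
  direction-count→∞ limit closes to 1%.
* **Effective radius only.** A single radius (per contrast) summarizes the
  whole distribution; recovering P(r) itself is out of scope.
* **Calibration needs ground truth.** The T2 branch requires a specimen
  with a known radius distribution to determine ρ₂; material changes (the
  simulated low-ρ₂ outlier) are detectable only through an elevated
  calibration residual.
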