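# poremri

Pore-size estimation from spherical-mean diffusion–relaxation MRI of
cylindrical pores.

MRI can measure the size of micron-scale water-filled pores — hollow
axon-mimicking microfibers, and ultimately axons — but only as an
*effective radius*: the single "MRI-visible" radius whose one-cylinder
signal best matches the signal of the whole pore-size distribution P(r).
This package implements a unified forward model for the powder-averaged
(spherical-mean) signal of a distribution of cylinders and the two
estimators derived from it, together with the numerical machinery needed to
validate them against ground-truth radius distributions (e.g. from scanning
electron microscopy) and a synthetic phantom simulator so that the entire
pipeline is testable without any external data.

## The model

The spherical-mean signal of water inside a distribution of cylinders with
radii r ~ P(r), acquired with a PGSE sequence at b-value b and echo time TE,
is the volume-weighted mixture

    S̄(b, TE) = k ∫ P(r) r² S̄_Rel(TE, r) S̄_Diff(b, r) dr / ∫ P(r) r² dr

with

* relaxation factor S̄_Rel = exp(−TE/T2i(r)), where the intra-pore
  transverse relaxation time follows the Brownstein–Tarr surface relation
  1/T2i = 1/T2b + 2ρ₂/r (T2b = bulk water T2, ρ₂ = surface relaxivity);
* diffusion factor S̄_Diff(b, r) = (√π/2) e^(−b·D⊥) erf(√(b·(D∥−D⊥))) /
  √(b·(D∥−D⊥)), the powder average of an axisymmetric tensor whose radial
  diffusivity D⊥(r) follows the van Gelderen Gaussian-phase-distribution
  series for restricted diffusion in a cylinder (18 terms by default).

Two limits give the two practical estimators:

* **T2 branch** (multi-TE at fixed b): treat S̄_Diff as constant, fit
  K·exp(−TE/T2i), invert T2i into a radius through the surface relation.
  Requires calibrating ρ₂ against a known radius distribution.
* **Diffusion branch** (multi-b at fixed TE, the spherical-mean power-law
  route): treat S̄_Rel as constant and fit β·S̄_Diff(b, r) with the full
  van Gelderen D⊥(r) — the classical wide-pulse (Neuman) closed form
  D⊥ ∝ r⁴ is provided for comparison but is invalid for pores larger than
  a couple of microns at δ/Δ = 9/35 ms.

Because each branch weights P(r) differently, the ground-truth reference is
itself contrast-specific: the package discretizes the mixture integral over
the measured radii (weights rᵢ²/Σrⱼ²), synthesizes the relaxation and
diffusion series of the distribution, and fits the one-cylinder models to
them, giving r_eff-SEM-R and r_eff-SEM-D. The first-order approximation
r_eff ≈ ⟨r²⟩/⟨r⟩ and the wide-pulse moment formula (⟨r⁶⟩/⟨r²⟩)^¼ are also
provided.

## Worked example

```python
import numpy as np
import poremri as pm

# 1. a synthetic phantom: heavy-tailed radius distribution, mean ~1.07 um
spec = pm.phantom_preset("phantom1")
sample = pm.sample_radii(spec, seed=7)

# 2. simulate its six-TE acquisition (b=5000 s/mm2, 48 directions, SNR 34)
ds = pm.simulate_dwi(sample, spec, scheme=pm.phantom_scheme("t2"),
                     snr=34.0, seed=7, n_voxels=25)
tab = ds.spherical_mean_table().sort_values("TE_ms")
series = pm.SphericalMeanSeries("TE", tab["TE_ms"].to_numpy(),
                                tab["mean"].to_numpy())

# 3. calibrate the surface relaxivity against the known radii
cal = pm.calibrate_rho2(series, sample, T2b=3000.0)

# 4. T2 branch: mono-exponential fit, then invert into a radius
fit = pm.fit_monoexp_t2(series)
relax = pm.RelaxationParams(T2b=3000.0, rho2=cal.rho2)
r_mri = pm.radius_from_t2(fit.T2i, relax)

# 5. distribution-level effective radius for comparison
synth = pm.synth_relaxation_series(sample, series.axis, relax)
r_sem = pm.fit_single_cylinder_relaxation((series.axis, synth), relax).r_eff
```

This prints (via the obvious `print` statements):

```
fibers: 11618, mean radius: 1.063 um
calibrated rho2: 3.17 nm/ms
intra-pore T2: 201.9 ms  ->  r_eff (MRI, T2 branch): 1.372 um
r_eff from the radius distribution: 1.371 um
moment-ratio approximation <r^2>/<r>: 1.228 um
```

The MRI-side estimate (1.372 μm) agrees with the distribution-level
effective radius (1.371 μm) to 0.1%: with a per-specimen calibrated ρ₂ the
T2 branch closes almost perfectly on the volume-weighted ground truth, even
on raw Rician-noised data. The calibrated ρ₂ (3.17 nm/ms) sits below the
simulation's ground-truth 3.5 nm/ms because the calibration absorbs the
radius-dependent diffusion weighting and the Rician floor of the magnitude
data — the same consistent-estimator mechanism operates on real
acquisitions. The moment ratio ⟨r²⟩/⟨r⟩ tracks the effective radius to
within ~12% here.

A command-line surface wraps the same operations:

```
poremri simulate --preset phantom1 --seed 7 --out sim/
poremri calibrate --series series.csv --radii radii.csv --t2b 3000 --out cal.json
poremri fit-t2 --series series.csv --rho2 3.7 --out t2.json
poremri fit-dmri --series bseries.csv --out dmri.json
poremri sem-reff --radii radii.csv --rho2 3.7 --out sem.json
poremri compare --pairs pairs.csv --out cmp.json
```

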