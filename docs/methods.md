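# Methods

## Model and assumptions

The package models pneumatic extrusion of a hydrogel through a cylindrical
nozzle under four assumptions:

1. **Power Law rheology.** Viscosity η = K γ̇ⁿ⁻¹ with K > 0 and 0 < n ≤ 1.
   The closed-form flow rate Q(ΔP) = π (ΔP/2KL)^(1/n) R^(3+1/n) / (3+1/n)
   follows from fully developed laminar flow with no wall slip and no yield
   stress. n = 1 is admitted as the Newtonian limit so the implementation
   can be checked against Hagen–Poiseuille; Herschel–Bulkley (yield-stress)
   behaviour, tapered nozzles and temperature dependence are out of scope.
2. **Empirical swell law.** The extrudate-swell ratio B = R_ex/R is taken as
   B = c₁ + c₂ τ_wᵝ with c₁ > 0, c₂ ≥ 0, β > 0, where τ_w = RΔP/2L. This is
   a descriptive fit over the observed stress range, not a viscoelastic
   theory; extrapolating it far beyond the calibrated τ_w range is
   unsupported.
3. **Volume conservation.** The strand neither gains nor loses volume
   between the nozzle exit and deposition: π R_ex² v_ex = Q = π R_p² v_p.
   This ignores swelling/drying, strand rupture at high stretch and
   deformation on the substrate.
4. **Plumb, quasi-steady hanging filaments.** Extrusion speed is defined as
   the descent speed of the free strand's tip while the filament is short
   enough (≤ 10 mm by default) that its own weight does not stretch it.

The parameter optimization index POI = 1/(2 R_p τ_w) is computed literally
in SI (units Pa⁻¹ m⁻¹), with no renormalization; it is meaningful for
ranking settings, not as an absolute scale.

## Parameters that matter

| parameter | units | default | role |
|---|---|---|---|
| K, n | Pa sⁿ, – | 222, 0.23 | fitted flow constants of the reference hydrogel |
| c₁, c₂, β | –, Pa⁻ᵝ, – | 1.57, 1.38e-10, 3.15 | fitted swell constants |
| R, L | m | 0.2065e-3, 12.7e-3 | 22G half-inch blunt needle |
| density | kg/m³ | 1000 | converts weighed mass to volume; configurable because the gel's density is rarely reported |
| max_length | m | 10e-3 | speed filter: intervals whose *starting* length exceeds this are discarded |
| max_segments | – | 2 | speed filter: filaments after the second rupture are discarded |
| rupture drop fraction | – | 0.5 | a >50 % length drop between 250 ms frames is read as a rupture |

All internal quantities are SI; files and the CLI use kPa/mm/g with
conversion confined to `extruflow.units` and `extruflow.io`.

## Fitting

Both fits minimize unweighted squared residuals on the natural data scale
(Q and B, not their logs) with the Nelder–Mead simplex
(`scipy.optimize.minimize`, `xatol` 1e-12, `fatol` 1e-10, ≤ 10 000
iterations), using replicate means; replicate SDs are carried for reporting
only.

- Flow fit: search over (log K, log n), started from the log-log regression
  of Q̄ on ΔP (slope = 1/n; K from per-point inversion at that n, combined
  by geometric mean). An optimum within 1e-6 of n = 1 is snapped to the
  Newtonian limit.
- Swell fit: search over (c₁, log a, log β) where a = c₂ τ_refᵝ is the
  stress-driven amplitude at τ_ref = max observed τ_w. This enforces c₂ ≥ 0
  and β > 0 by construction and keeps the amplitude O(1) even though c₂
  spans decades. Start: c₁ = min B, β = 3, amplitude from the largest-stress
  point. A flat dataset (c₂ = 0) drives the amplitude toward zero smoothly.

Identifiability: with seven stress values spanning only a factor ~1.9,
c₂ and β trade off strongly along a ridge; the fitted *curve* B(τ_w) and c₁
are well determined long before β is. Monte-Carlo runs under the default
noise show median absolute errors of ~0.004 on n, ~2 % on K and ~0.04 on c₁,
but ~0.4–0.7 on β — consistent with the linearized (Fisher) spread of β̂
given ~1 % noise on B, which is dominated by the flow assay's 5 % CV over
five replicates. A tighter β requires either more pressures, a wider stress
range or a more precise flow measurement, not a better optimizer: the
simplex optimum coincides with a gradient-based refit started at the truth.

## Trace analysis

Speeds are forward finite differences over one frame interval, computed
within rupture-delimited segments only and never smoothed. The ≤ 10 mm
filter applies to the left endpoint of each difference interval (the choice
of endpoint shifts the retained set by at most one frame). Because the mean
of consecutive forward differences telescopes to an endpoint difference,
pixel noise largely cancels from the speed estimate: its standard error is
≈ 2σ_px/(N Δt) per run of N frames, well under 1 % of v_ex at the default
noise.

## Synthetic data generator

The generator emulates the bench protocol: 7 pressures (70–130 kPa in
10 kPa steps), 5 replicate 60 s extrusions weighed per pressure, and
hanging-filament traces sampled every 250 ms until shortly after the second
rupture.

- Flow noise is multiplicative Gaussian on the collected mass (CV 5 % by
  default), standing in for balance and dispensing variability.
- Trace noise is additive Gaussian on lengths (SD 0.05 mm = 1 px at the
  default calibration of a 12.7 mm needle spanning 254 px), standing in for
  pixel quantization; lengths are clipped at zero.
- Beyond a 10 mm onset the tip accelerates as
  dℓ/dt = v_ex (1 + g·(ℓ − ℓ_onset)) with g = 50 m⁻¹ — a **phenomenological
  stand-in** for gravity-driven stretching, chosen so the tip speed roughly
  doubles by 30 mm. It exists so the short-filament filter has a regime to
  exclude; it is not a mechanical model of filament thinning, and no claim
  is made that its speed-versus-length shape matches real filaments.
- Ruptures occur when the length crosses a threshold drawn uniformly from
  30–35 mm, after which the length resets to zero. Real rupture mechanics
  (necking, yield) are not modelled.
- Frames are rendered as a bright vertical bar (round(ℓ/px) rows below the
  tip row) on a noisy dark background — an idealized stand-in for real
  video frames: no lateral sway, no defocus, no intensity gradients.

All randomness derives from one integer seed via per-stream substreams
(`numpy` `default_rng([seed, stream, ...])`), so every artifact is
bit-for-bit reproducible. Consequently, passing recovery tests demonstrate
that the estimators are unbiased and correctly plumbed under the stated
noise model — not that they are robust to the systematic effects (density
error, meniscus effects, sway, manual measurement bias) present in real
recordings.

## Numerical choices and edge cases

- The validated problem sizes: 7 pressures × 5 replicates for flow; traces
  of ~50–300 samples per pressure; Monte-Carlo recovery uses 50 independent
  seeds, and 100 repeats for the single-fit studies.
- Rupture detection uses a relative drop (50 %) rather than an absolute
  one, so it is calibration-independent; a sub-50 % dip never splits a
  segment, which makes segmentation immune to pixel noise.
- `segment_trace` of a monotone trace returns a single segment; a blank
  frame measures length 0; a zero-amplitude swell law is constant;
  `plan_print` at R_p = R_ex returns exactly v_ex and flags the matched
  regime at 1e-9 relative tolerance.
- G-code uses a serpentine strut order per layer to shorten travel; both
  footprint edges always receive a strut, so spacing = footprint degenerates
  to the 4-line boundary frame. Coordinates are written at 0.1 µm
  resolution, far below strand dimensions.
- The scaffold's physical dimensions (20 mm square, 5 mm pitch, 3 layers,
  0.41 mm layer height) are arbitrary but representative defaults — the
  construct geometry is the user's design choice, not a model output.

## Known limitations

Single cylindrical-nozzle geometry; one empirical swell law form; no
uncertainty quantification on fitted constants beyond the Monte-Carlo
studies; no prediction of strand rupture when v_p ≫ v_ex, coiling when
v_p < v_ex, or strand fusion/sagging after deposition. The regime flag
(stretched/matched/compressed) is metadata for the operator, not a
printability guarantee.
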