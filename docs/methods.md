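# Methods

`plaquemorph` characterises atherosclerotic carotid plaque specimens along
three coupled axes: the 3D morphology of calcification from micro-CT, bulk
biochemical composition from ATR-FTIR, and tensile behaviour from uniaxial
testing. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
establish.

## Micro-CT morphometry

**Data model.** A `VoxelVolume` is a 3D grid of 16-bit grey values (GV) at
isotropic spacing (default 15.5 µm, the resolution of the scans this
pipeline models). An optional linear grey-value calibration
(`calibrate_grey_values`) maps measured GVs onto a reference scale by
ordinary least squares over material reference points (air / water /
hydroxyapatite phantom style); with two points the map interpolates them
exactly.

**Segmentation.** Fixed thresholds split the volume into background
(< 324 GV), plaque tissue (324–1249 GV) and calcification (≥ 1250 GV).
The published bands leave GV 1250 unassigned ("324–1249" and "> 1250"); we
assign it to calcification so the bands are contiguous. All thresholds are
configuration.

**Inclusion extraction.** Calcification components are maximal connected
sets at 26-neighbour connectivity by default (an agglomerate whose lobes
touch corner-to-corner is one inclusion); 6-connectivity is available.
Labelling is scipy's `ndimage.label`; it is property-tested against a
brute-force flood fill.

**Measurements per inclusion.**

* Volume V_p = voxel count × voxel volume (mm³).
* Equivalent diameter d = (6V_p/π)^{1/3} (µm): the diameter of the
  volume-equivalent sphere.
* Surface area A_p (mm²): marching cubes on the Gaussian-smoothed
  (σ = 1 voxel) binary component, with the isolevel chosen by bisection so
  that the mesh-enclosed volume equals V_p. Marching cubes at level 0.5 on
  the raw mask overestimates a digitised sphere's area by ~9% (staircase
  facets), which would bias sphericity to ~0.92 for true spheres; a fixed
  0.5 level on the smoothed field instead erodes small blobs (curvature
  shrinkage ~σ²/r). Matching the enclosed volume removes both biases:
  measured sphere areas are within ~1% for radii ≥ 8 voxels and sphericity
  of digitised spheres is within 0.01 of 1 down to ~3-voxel radii. The
  trade-off is edge rounding on sharp-cornered solids: a plate with crisp
  edges reads low by roughly (2 − π/2)·ρ per unit edge length (ρ ≈ 1.5σ),
  about −10% for a 20×14×10-voxel box, −5% at twice that size, and ~−3%
  for a realistic 1200×500×80 µm sheet at 15.5 µm voxels. σ is
  configuration. Components thinner than 2 voxels in any axis cannot be
  meshed and fall back to summed voxel-face area, flagged
  (`voxel_face_area_fallback`); note the face estimator overshoots curved
  surfaces by ~1.5×, which is why it is only a fallback.
* Sphericity ψ = π^{1/3}(6V_p)^{2/3}/A_p — 1 for a perfect sphere. Mesh
  discretisation can push ψ marginally above 1 for small near-spheres;
  values above 1 + `mesh_psi_tolerance` (default 0.02) are flagged rather
  than clipped.
* Principal extents (l ≥ w ≥ t, µm): peak-to-peak spans of voxel-centre
  coordinates projected on the eigenvectors of the coordinate covariance,
  plus one voxel size for finite voxel extent. Accurate for axis-aligned
  solids; re-voxelised rotated solids recover extents to ~15%.

**Classification** (applied in order, so classes are mutually exclusive):

1. *spherical* — d < 300 µm and ψ ≥ ψ_min (default 0.85);
2. *sheet* — l/w ≥ r and w/t ≥ r (default r = 2);
3. *irregular* — everything else (ties fall here).

The 300 µm rule uses the volume-equivalent diameter by default ("less than
300 µm" for particles whose size is derived from measured volume); the
longest principal extent is available as an alternative convention.
ψ_min = 0.85 sits well below what the area estimator scores for digitised
true spheres (≥ 0.97) and above typical agglomerates (≤ 0.85). Single-voxel
components are retained but flagged low-confidence; no noise filter is
applied.

**Specimen summary.** CVF = calc volume / (calc + tissue volume) ∈ [0, 1];
undefined (flagged) when both masks are empty. Per-class counts and totals
complete the structural record.

## FTIR composition ratios

Peak area of an absorbance band is proportional to component
concentration, so composition is summarised by Lip:Col and Calc:Col —
areas of the lipid and calcification bands over the collagen band. Default
integration windows sit on standard mid-IR assignments: lipid ester C=O
1710–1780 cm⁻¹, collagen amide I 1600–1700 cm⁻¹, hydroxyapatite phosphate
ν3 960–1100 cm⁻¹. These windows are configuration, not constants: the
instrument software that produced the published ratios does not document
its windows, so published per-specimen ratios are emulation targets, not
recomputation targets.

Integration is trapezoidal after subtracting a linear baseline chord
anchored at the window endpoints; each anchor is the mean of the 5
innermost samples at that end (single-sample anchors let one noisy point
tilt the whole chord — with 0.005 absorbance noise the chord-area noise on
the 140 cm⁻¹ calcification window would otherwise be of the same order as
a weak band). Negative net areas are floored at zero with a warning. Ratios
from multiple measurement locations are combined as the mean of ratios
(matching per-location ratio averaging), not the ratio of mean areas.

## Mechanics

Stretch λ = (L0 + d)/L0; Cauchy stress σ = (F/A0)·λ under the
incompressibility assumption standard for soft tissue (engineering stress
F/A0 is available as configuration). Initial stiffness is the least-squares
slope of σ against (λ − 1) in a window, default λ ∈ [1.0, 1.1] (matching a
10%-of-gauge-length preconditioning regime); whether "initial stiffness"
is a tangent or a small secant is not decidable from published tables, so
the window is configuration. Ultimate strength is the global stress maximum
(first occurrence on ties). Stiffness groups use half-open breakpoints
(default 1.0, 2.0 MPa), placed to separate the three observed stiffness
levels (~0.6–0.75, 1.25–1.6, ~3.8 MPa): LS < 1.0 ≤ MS < 2.0 ≤ HS.

## Synthetic ground truth

The study's raw scans, spectra and tensile records are not deposited, so
validation uses generators with known truth.

* **Voxel phantoms** place spheres, thin plates and agglomerates (unions of
  ≥ 3 overlapping spheres — "randomly shaped masses" are otherwise
  unconstrained) inside a tissue box, voxelise by centre-inside tests, and
  draw grey values per class (means 100 / 700 / 1800 GV, Gaussian noise,
  rounded to 16-bit). The default validation phantom is a 200³ grid at
  15.5 µm with 16 spheres of 100–250 µm, 2 sheets of 1200×500×80 µm and 2
  five-lobe agglomerates under 30 GV noise. Sphere and sheet truth
  volumes/areas are analytic; agglomerate truth is numeric (4 µm
  supersampled voxelisation) since sphere unions with triple overlaps have
  no closed form. What the phantoms do **not** emulate: partial-volume
  blur, beam hardening, reconstruction artefacts, or anatomically shaped
  tissue — a green recovery test establishes the measurement chain, not
  robustness to scanner physics.
* **Spectra** are sums of Gaussian (optionally Lorentzian) bands of
  specified integrated area on the 4000→700 cm⁻¹ grid at 2 cm⁻¹, plus a
  linear baseline and noise. Default band positions/widths (lipid 1745/16,
  collagen 1655/24, calcification 1030/40 cm⁻¹ FWHM) keep every band
  ≥ 3.4σ inside its default window, so windowed quadrature recovers the set
  area to well under 1%. Noisy-recovery properties use a collagen area of
  5 absorbance·cm⁻¹ (amide I peak height ≈ 0.2), the realistic ATR tissue
  scale; at much weaker scales a 0.005 absorbance noise floor is comparable
  to a ratio-0.1 band and no estimator recovers it.
* **Tensile curves** follow σ(λ) = a(e^{b(λ−1)} − 1) — the standard
  soft-tissue stiffening stand-in (small-strain modulus a·b) — truncated at
  a rupture stretch and inverted through the same Cauchy convention the
  analysis uses, so round-trips are exact at zero noise. Three of the six
  published specimens have initial stiffness *above* their secant modulus
  (concave curves past the toe); a stiffening law cannot reproduce those
  rows' stiffness and rupture point simultaneously, so specimen emulation
  targets stiffness + rupture stretch, and the cohort-mean rupture point
  (0.40 MPa at λ = 1.44) is reproduced by construction on a dedicated
  curve. Note that for b > 0 the [1.0, 1.1]-window secant exceeds the λ = 1
  tangent a·b by ≈ b·0.05 — visible in the analysis output and expected.

## Study aggregates

Per-specimen results are joined one row per specimen; group labels are
re-derived from stiffness and cross-checked. Summaries use the sample
standard deviation (n − 1), which reproduces the published dispersion
values (0.09 MPa stress SD, 0.13 stretch SD) where the population SD does
not. Groups of size one report SD = 0, flagged. Missing geometry counts
("-" in the published table) parse as zero. The mean of the published
two-decimal peak-stress column is 0.392, not the published 0.40 — the study
evidently averaged unrounded raw data — so the mean stress is reported but
not asserted against 0.40. The SEM-EDX check passes a region as
calcification (hydroxyapatite-like) when its molar Ca:P ≥ 10/6, within a
0.005 rounding tolerance so a ratio printed as 1.67 counts as equivalent;
mass-percent inputs convert via molar masses (Ca 40.078, P 30.974).

## Known limitations

* Surface areas of sharp-edged solids are biased low by edge rounding
  (see above); published per-specimen surface areas were produced by a
  different (undocumented) meshing chain and are not comparison targets.
* "Spatial distribution" of inclusions is reported only as centroids.
* No partial-volume handling: a voxel is one class.
* Calibration is a linear GV map, not a density calibration.
* No hypothesis testing across stiffness groups (n = 6 specimens; the
  source study reports none either).
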