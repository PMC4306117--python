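# plaquemorph

Multi-modal characterisation of atherosclerotic carotid plaque: 3D
morphometry of calcification from micro-CT, biochemical composition ratios
from ATR-FTIR, and stress–stretch analysis of uniaxial tensile tests — the
workflow used to relate a plaque's calcification structure to its
mechanical stiffness.

Who it is for: researchers quantifying vascular calcification in
reconstructed micro-CT volumes, or relating plaque composition and
structure to tensile behaviour, who need a tested, scriptable version of
the full measurement chain with synthetic ground-truth validation.

## What it computes

**Micro-CT morphometry** (`plaquemorph.morphometry`). A grey-value volume
is segmented with fixed thresholds — plaque tissue 324–1249 GV,
calcification ≥ 1250 GV — and each connected calcification component
(26-connectivity) is measured:

- volume V_p (mm³) and marching-cubes surface area A_p (mm²),
- sphericity  ψ = π^⅓ (6V_p)^⅔ / A_p,
- volume-equivalent diameter d = (6V_p/π)^⅓,
- principal extents l ≥ w ≥ t,

and classified as **spherical** (d < 300 µm, ψ ≥ 0.85), **sheet**
(l/w ≥ 2 and w/t ≥ 2) or **irregular** agglomerate. The specimen-level
calcification volume fraction is CVF = V_calc / (V_calc + V_tissue).

**FTIR composition** (`plaquemorph.ftir`). Baseline-corrected peak areas
over configurable windows (lipid ester C=O, collagen amide I,
hydroxyapatite phosphate ν3) give Lip:Col and Calc:Col ratios, averaged
over measurement locations.

**Mechanics** (`plaquemorph.mechanics`). Force–displacement records become
Cauchy stress–stretch curves (σ = F·λ/A0 under incompressibility); the
initial stiffness (least-squares slope for λ ∈ [1.0, 1.1]), ultimate
strength (σ, λ at the peak) and a stiffness group label (LS / MS / HS at
1.0 and 2.0 MPa breakpoints) are extracted.

**Study reporting** (`plaquemorph.report`) joins the three per-specimen
records and computes group summaries, geometry-class totals, CVF order
statistics and the SEM-EDX hydroxyapatite stoichiometry check
(molar Ca:P ≥ 10/6). **Synthetic generators** (`plaquemorph.synthetic`)
provide voxel phantoms, spectra and tensile curves with known ground truth
for every stage.

See `docs/methods.md` for models, parameter defaults and numerical choices.

## Worked example

```python
from plaquemorph import synthetic as syn
from plaquemorph.morphometry import run_morphometry

spec = syn.sample_phantom_spec(seed=1)      # 200^3 voxels at 15.5 um:
volume, truth = syn.generate_phantom_volume(spec)  # 16 spheres, 2 sheets,
report = run_morphometry(volume)                   # 2 agglomerates, 30 GV noise
print(report.class_counts, round(report.cvf, 5))
```

prints

```
{'spherical': 16, 'sheet': 2, 'irregular': 2} 0.00879
```

— the pipeline recovers every inclusion's geometry class and the phantom's
calcification volume fraction (0.88% of the tissue volume here) from the
noisy volume. The numbered drivers under `analysis/` run the same stages
with narrative output and write tables under `results/`:

```bash
python analysis/01_phantom_morphometry.py --seed 1   # phantom -> morphometry recovery
python analysis/02_ftir_ratios.py --seed 1           # spectra -> composition ratios
python analysis/03_mechanics_summary.py --seed 1     # tensile curves -> stiffness/groups
python analysis/04_study_aggregates.py               # published tables -> aggregates
```

For example, `04_study_aggregates.py` recomputes from the packaged
per-specimen tables: 505 spherical particles across the six plaque
sections, CVF ranking 0.52 (stiffest plaque) over 0.32 (a low-stiffness
plaque), and ultimate strength stretch 1.44 ± 0.13 with stress SD
0.09 MPa.

A `plaquemorph` CLI wraps the same stages
(`plaquemorph synth|morpho|ftir|mech|report ... --help`).

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch on freshly
generated inputs — phantom volume through morphometry, synthetic spectra
through ratio recovery, synthetic tensile curves through summarisation,
plus the packaged-table aggregates — printing each stage's result and
writing a JSON results object:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
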