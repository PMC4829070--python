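# pgtkit

Prompt gamma-ray timing (PGT) simulation and analysis for in-vivo proton
range verification, plus the detector-physics primitives of a prompt-gamma
Compton camera.

The package models a proton pencil beam slowing down in a heterogeneous
layered target (continuous slowing down approximation with a Bragg–Kleeman
range–energy law), predicts the detection-time spectrum of prompt gamma rays
at a timing detector (proton transit time plus photon time of flight,
smeared by detector and bunch time spreads and folded over the accelerator
RF period), and extracts range information back out of such spectra:
distribution moments, trailing-edge localization, time-to-depth inversion,
and range-shift detectability versus delivered proton statistics.  A second
module group covers block-detector characterization: empirical energy/time
resolution fits, the background-suppression figure of merit of pulsed-beam
timing, photon attenuation tables, Compton scattering kinematics with
cone-of-response backprojection, and Anger-logic flood maps.

## Layout

| module              | contents |
|---------------------|----------|
| `pgtkit.transport`  | materials, layered phantoms, CSDA energy/velocity/range/transit time and its inverse |
| `pgtkit.model`      | beam/detector specs, analytic expected spectra, Monte Carlo event sampling, bunch-phase drifts |
| `pgtkit.analysis`   | moments, background subtraction, trailing edge, edge-shift → range-shift conversion, time→depth profiles, detectability curves |
| `pgtkit.detector`   | resolution fits (LSO2/BGO1), FoM, attenuation tables (Pb/CsI/water), Compton cones, backprojection, Anger logic, flood maps |
| `pgtkit.io`         | YAML run configs, phantom/spectrum/event file formats, JSON-lines reports |
| `pgtkit.fixtures`   | canned geometries: full 400-mm PMMA at 230 MeV, 5-mm air cavity and 20-mm bone insert at f = 169 mm, 106-MHz beam |
| `pgtkit.cli`        | the `pgt` command |

## Command line

```sh
# sample a PGT spectrum for the full PMMA target (or a phantom spec file)
pgt simulate --phantom wpe_homogeneous_230 --energy 230 --nprotons 1e8 \
    --efficiency 0.5 --seed 1 -o ref.tsv
pgt simulate --phantom wpe_cavity_5mm --energy 230 --nprotons 1e8 \
    --efficiency 0.5 --seed 2 -o cav.tsv

# moments / edge / depth profile, and the edge shift between two spectra
pgt analyze ref.tsv --phantom wpe_homogeneous_230 --energy 230
pgt compare ref.tsv cav.tsv --phantom wpe_homogeneous_230 \
    --test-phantom wpe_cavity_5mm --energy 230

# range-shift detectability versus proton count
pgt detectability --energy 230 --efficiency 0.5 --ngrid 1e7,1e8 --seed 1

# detector characterization
pgt detector fom --preset LSO2 --energy 4 --bunch-fwhm 2 --period 9.434
pgt detector resolution --preset BGO1 --energy 4.4
pgt detector floodmap --preset LSO2 --energy 4.4 -o floodmap.tsv
pgt compton backproject events.tsv --grid -40:40:41 --plane-z -100
```

Phantom spec files are plain text, one `material thickness_mm` per line
(`#` comments); built-in materials are `pmma`, `air`, `bone`, `water`.

## Notes on the physics model

- Stopping power is a water-referenced Bragg–Kleeman law
  (`p = 1.77`, coefficient calibrated to a 330-mm range at 230 MeV); each
  material scales it by density and a water-equivalence factor (PMMA 1.16
  and cortical bone 1.57 relative linear stopping power).  Measured
  stopping-power tables can override the analytic law per material.
- Emission density along the track is box-like: local density times a
  per-material yield factor, zero beyond the range; 0.16 prompt gammas per
  fully stopped proton by default, scaled down for shoot-through targets.
- Bundled photon attenuation grids (Pb, CsI, water) are total
  mass-attenuation coefficients assembled from standard compilations
  (log-log interpolated); see `src/pgtkit/data/`.
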