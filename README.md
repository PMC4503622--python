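# vesishape

Shape mechanics and quantitative microscopy of giant unilamellar
vesicles (GUVs), built for studies in which an amphiphile (for example
a PEG-conjugated lipid) inserts into the outer membrane leaflet and
drives the vesicle through a sequence of shape transformations —
sphere, disc, cigar, budded dumbbell — that are scored in fluorescence
micrographs by the major–minor axis ratio of each vesicle.

The package covers both halves of such a study:

* **Theory.** A bilayer-coupling (BC) bending-energy solver computes the
  vesicle shape of minimum reduced bending energy
  `w_b = (1/16π) ∮ (C₁+C₂)² dA` at fixed reduced volume
  `v = V / ((4π/3) R_A³)` and area difference `Δa = M / (4π R_A)`,
  with `M = ½ ∮ (C₁+C₂) dA` and `R_A = √(A/4π)` (all three equal 1 for
  a sphere; the bending rigidity κ_b factors out).  Shapes are
  axisymmetric star-shaped surfaces `r(θ) = Σ a_l P_l(cos θ)`
  (spherical-harmonics parameterization), minimized by SQP with
  complex-step gradients, classified into
  sphere / stomatocyte / oblate / prolate / pear / pin, and tabulated
  into a `(Δa, v)` shape library.
* **Experiment emulation and analysis.** A synthetic-microscopy
  generator renders dye-filled vesicles (single planes, multi-vesicle
  frames, confocal Z-stacks) with exact ground truth; the analysis
  pipeline segments micrographs (CLAHE + Otsu), fits ellipses, applies
  the 5–20 µm size filter, computes M-m ratio statistics and
  histograms, reconstructs 3-D surfaces from Z-stacks to measure `v`,
  and matches observed silhouettes against the shape library.

## Worked example

```python
from vesishape import (ShapeConstraints, minimize_shape, silhouette_mm_ratio,
                       PopulationModel, ImagingConfig, sample_population,
                       measure_frame, size_filter, population_statistics)

# 1. theory: minimum-bending-energy shape at v = 0.80, da = 1.12
sol = minimize_shape(ShapeConstraints(0.80, 1.12))
print(sol.shape_class)               # prolate
print(round(sol.wb, 4))              # 1.5447
print(round(silhouette_mm_ratio(sol), 3))   # 2.016

# 2. emulated assay: 300 vesicles at an intermediate dose
model = PopulationModel(n_vesicles=300, seed=0)
frames, truth = sample_population(model, c=20.0, config=ImagingConfig(seed=1))
ratios = []
for frame in frames:                 # 12 rendered frames
    ratios += [m.mm_ratio for m in size_filter(measure_frame(frame, pixel_size=0.2))]
stats = population_statistics(ratios)
print(stats.n, round(stats.mean_ratio, 3), round(stats.sd_ratio, 3))
# 280 1.239 0.348
print(round(model.true_mean_ratio(20.0), 3))
# 1.25
```

The simulated shape at `(v, Δa) = (0.80, 1.12)` is a prolate with
reduced bending energy 1.54 (a sphere scores 1) whose silhouette has a
2.0 major–minor ratio.  The emulated population at dose 20 (where half
the vesicles deform) yields 280 in-size-range measurements whose mean
M-m ratio, 1.239 ± 0.02, agrees with the generator's closed-form
mixture mean of 1.25; the histogram peaks in the first bin because
undeformed spheres still dominate.

The command-line interface exposes the same steps
(`vesishape simulate | library | synth | quantify | reconstruct | match`);
run `vesishape --help`.

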