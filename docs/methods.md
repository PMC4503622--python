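# Methods

## Bilayer-coupling shape model

A vesicle is modeled as a closed fluid membrane minimizing the Helfrich
bending energy at fixed enclosed volume, fixed area, and fixed
integrated mean curvature.  The last constraint is the bilayer-coupling
(BC) closure: the two leaflets of the bilayer do not exchange lipid, so
the area difference between them — proportional to `M = ½∮(C₁+C₂)dA` —
is set by composition, not by mechanics.  The BC model predicts
continuous (second-order) shape transformations, which is what motivates
its use for gradual sphere → prolate → budded sequences; the
spontaneous-curvature and area-difference-elasticity models, which
predict discontinuous jumps, are out of scope.

All quantities are reported scale-free, normalized so a sphere scores 1:

| symbol | definition | sphere |
|---|---|---|
| `v`   | `V / ((4π/3) R_A³)`, `R_A = √(A/4π)` | 1 |
| `Δa`  | `M / (4π R_A)` | 1 |
| `w_b` | `(1/16π) ∮ (C₁+C₂)² dA` | 1 |

The bending rigidity κ_b multiplies `w_b` only as an overall scale
(`W_b = 8π κ_b w_b`) and never enters numerically.  `w_b ≥ 1` for every
closed surface (Willmore bound).

### Parameterization and quadrature

Shapes are axisymmetric and star-shaped about an interior origin:
`r(θ) = Σ_{l=0}^{L} a_l P_l(cos θ)` (zonal Legendre series; odd modes
carry up–down asymmetry).  Surface area, volume, `M` and `w_b` are
evaluated by Gauss–Legendre quadrature in `u = cos θ` at order
`4(L+1)`, which is exponentially convergent for these smooth profiles;
doubling the order changes the reported measures at machine-precision
level for energy-minimizing shapes (this is a tested property).
Spheroids evaluated through the same quadrature reproduce their
closed-form area and volume to 1e-15 relative, which serves as the
module's independent oracle.

**Degree cutoff.** The default is `L = 24`.  This is deliberately high:
the competition between the up–down-symmetric dumbbell and the
asymmetric pear near the budding line is resolution-limited, because
truncation penalizes the elongated symmetric shape more than the
compact pear.  At `(v, Δa) = (0.69, 1.39)` the winning branch's
lobe-volume ratio converges 0.59 (L=12) → 0.78 (L=20) → 0.89 (L=24);
below L≈24 the solver reports a spuriously asymmetric bud.  Away from
the budding line L=12 is adequate and is used in fast unit tests.

**Star-shape guard.** Iterates must satisfy `r(node) ≥ 0.05·a₀`,
imposed as linear inequality constraints.  This bounds the
representable class: deeply invaginated stomatocytes (an inner sphere
connected through a narrow mouth) are not star-shaped and are honestly
reported as non-converged rather than approximated.

### Constrained minimization

The solver is sequential quadratic programming (scipy SLSQP) on the
coefficients, with equality constraints on `v` and `Δa` and the scale
gauge `A = 4π` (the problem is scale-free, so one more constraint is
needed to pin the scale).  Gradients of the energy and of every
constraint are obtained by batched complex-step differentiation of the
quadrature — exact to machine precision, with one complex matrix
product per evaluation.  SLSQP occasionally stalls in its line search;
each solve is therefore restarted from its stopped iterate up to three
times.

The energy surface at fixed `v` is multi-welled in `Δa` (at `v = 0.80`:
an oblate well at `Δa ≈ 1.034`, a prolate well at `Δa ≈ 1.127`, a
barrier between, and stomatocyte / budded families beyond), and SQP
from naive perturbed-sphere starts routinely misses wells.  The search
therefore follows branch structure explicitly and deterministically:

1. spheroid prototypes matched to the target `v` are relaxed with `Δa`
   free, giving the oblate and prolate branch bottoms;
2. each bottom is walked to the target `(v, Δa)` by adaptive homotopy
   (linear path, 0.01 steps shrinking to 0.002 on failure), both within
   the even-degree (symmetric) subspace and in the full space with
   periodic degree-3 nudges that let symmetry-broken branches
   (stomatocyte, pear) take over when they are lower;
3. in the budded regime (`Δa ≥ 1.15`) two-sphere dumbbell prototypes,
   and in the invaginated regime (`Δa ≤ 1.0`) a dimpled-sphere
   prototype, are walked in from their own natural `(v, Δa)`.

The lowest-energy converged walk wins.  Energy differences below 1e-3
are treated as a numerical degeneracy, and within that band the most
symmetric representative is preferred: near the budding line the
symmetric and asymmetric branches become degenerate, and truncation
noise would otherwise flip the reported symmetry arbitrarily.

Constraints are met within 1e-4 (configurable).  `minimize_shape` is
deterministic: fixed start family, fixed step rules, no randomness.

### Classification

Rules operate on the meridian `(ρ(θ), z(θ))` and are threshold-robust
because the energy-minimizing families themselves have soft features
(the relaxed BC prolate at `v = 0.8` carries a genuine ~10% equatorial
waist, and mild biconcavity is part of the oblate branch):

* **sphere** — max radial deviation from the mean < 1%;
* **stomatocyte** — a one-sided inward polar fold: `z(θ)` rises by at
  least 5% of the body height inside one polar region and not the
  other.  A biconcave discocyte folds both poles and remains oblate;
* **pin / pear** — an interior neck (a minimum of ρ between two maxima
  at least 15% of max-ρ deep).  The lobe volumes on either side of the
  neck plane decide the name: near-equal lobes (ratio ≥ 0.8) are pins
  (symmetric dumbbells), unequal lobes are pears.  Both thresholds are
  configurable;
* **oblate / prolate** — otherwise, by equatorial vs axial extent.

The solver's budded solutions show that bud symmetry increases with
`Δa` at fixed deflation: at `(0.83, 1.30)` the minimum is a strongly
asymmetric bud (lobe ratio ≈ 0.07), at `(0.69, 1.39)` a symmetric
dumbbell (≈ 1.0).  At `(0.80, 1.25)` the minimum is an asymmetric
bowling-pin-like bud with lobe ratio ≈ 0.12, which under the
lobe-ratio naming above reads "pear" rather than "pin" — worth knowing
when comparing against by-eye taxonomies of the same sequence.

`silhouette_mm_ratio` reports max/min of (axial extent, equatorial
extent) of the section through the symmetry axis, following the
imaging convention that a deformed vesicle settles with its long axis
in the focal plane.  For oblates this in-plane-axis convention reads
the disc edge-on and may overstate what a top-down micrograph would
show; the convention is deliberate and documented rather than resolved.

### Shape library

`build_library` walks a half-open `(Δa, v)` grid — `[0.5, 1.6) ×
[0.6, 1.0)` at 0.01 steps enumerates exactly 110 × 40 = 4400
conditions (inclusive stops would give 4551) — ascending `Δa` within
each `v` row, warm-starting each condition from its converged left
neighbor and falling back to the full multi-start search.  Budded
shapes are reachable by continuation but not directly from a sphere,
which is why rows ascend.  After two consecutive failures in a row
(the deep-stomatocyte regime), the fallback shrinks to a single
dimpled-sphere attempt until the row converges again.  Every condition
is recorded; failures go to `non_converged` and the entry count always
equals the grid cardinality.  Near and beyond the geometric feasibility
frontier the constrained minimum within the star-shaped class can be a
strained, high-energy shape (e.g. a wiggly near-sphere manufacturing
extra `Δa`); such entries are stored as computed — the library reports
the model's answer, not a curated subset.

## Synthetic microscopy

The generator emulates fluorescence imaging of dye-filled GUVs: bright
filled interiors (the fluorophore is encapsulated in the lumen, so
vesicles are discs, not rings), dark background, isotropic Gaussian
blur as a PSF stand-in, additive Gaussian noise (Poisson optional),
0.2 µm/pixel lateral sampling and 1 µm axial steps for Z-stacks.
Rasterization is anti-aliased (4×4 subpixel coverage): hard
pixel-center sampling quantizes an object's width independently along
x and y and imprints a spurious percent-level ellipticity on small
vesicles that no downstream estimator can undo.

Populations mix undeformed spheres with deformed vesicles (prolate
spheroids lying in the focal plane at random in-plane orientation).
The deformed fraction follows a saturating dose response
`p_def(c) = c/(c + c_half)` with `c_half = 20` on the dose scale of the
emulated assay (doses 0–165); deformed aspect ratios follow
`1 + Gamma(2, 0.25)` (mean 1.5), with an optional narrow "budded" mode
at a configurable ratio in 1.5–2.5 to emulate a secondary histogram
peak.  Diameters are uniform on 5–20 µm.  The population mean M-m
ratio is available in closed form, which is what pipeline recovery is
tested against.  All randomness flows from one integer seed;
identical settings give bit-identical frames.

What the generator does **not** emulate: confocal PSF physics,
bleaching, membrane rings, vesicle motion between slices, debris,
lamellarity variation, or manual selection bias.  Passing recovery
tests therefore demonstrate the correctness of the measurement chain
on ideal-but-noisy data, not robustness to every real-microscopy
artifact.

## Micrograph analysis

Segmentation is CLAHE (contrast-limited adaptive histogram
equalization) followed by Otsu global thresholding, morphological
opening, hole filling and small-object removal — adaptive histogram
equalization is contrast enhancement, not a binarization, so the
explicit threshold step is required.  Because equalization distorts
the intensity ramp at object boundaries, each detected component is
then re-thresholded on the *original* image at the half level between
its interior median and local background median (the 50% contour of a
symmetrically blurred step sits on the true edge), on a 2× upsampled
neighborhood for subpixel accuracy.  Ellipse fits are moment-based
(normalized-second-moment convention); equivalent diameter is that of
the circle with the mask's area.  Components touching the frame border
are flagged and excluded from statistics by default.  Recovered M-m
ratios on synthetic frames are within 2% of ground truth (median
~0.2%, max 1.3–1.8% across seeds at 200 vesicles/population).

The Z-plane maximizing mask area is selected automatically (ties to
the lower index), replacing the manual plane choice of the emulated
protocol for reproducibility.  The size filter keeps equivalent
diameters in [5, 20] µm inclusive and is idempotent.  Histograms use
0.1-wide bins starting at 1.0; peaks are local maxima with prominence
≥ 20% of the tallest bin (zero-padded so boundary bins qualify).

## 3-D reconstruction

Single-vesicle Z-stacks are binarized slice by slice with the 2-D
segmenter, converted to a signed Euclidean distance field computed with
the physical voxel sizes (anisotropy is handled by geometry, never by
resampling), lightly smoothed (0.4 µm) and triangulated by marching
cubes at the zero level.  Smoothing a signed distance field is nearly
bias-free at the surface, unlike smoothing binary occupancy, which
erodes curved objects.  Meshes must be watertight; area is the triangle
sum, volume the signed-tetrahedron sum, and
`v = V/((4π/3)(A/4π)^{3/2})`.  On rendered 10 µm spheres at 0.2 µm/px
and 1 µm steps the reconstruction is within ~2% in area and ~4% in
volume; recovered `v` is within ±0.05 at a 1 µm step and ±0.02 at
0.5 µm.  Objects touching any stack face raise a clipped-object error;
multiple components raise an ambiguity error listing them.  No
correction is applied for gravity flattening of near-spheres.

## Silhouette matching

Observed masks or contours are matched to library entries by a
reconstructed metric (the emulated workflow matched by eye; result
metadata says so): both silhouettes are resampled, centroid-centered,
scaled to unit equivalent radius, principal-axis aligned, and compared
by RMS difference of radial profiles at 360 polar angles, minimized
over the 180° and mirror ambiguities.  An optional measured-`v`
restriction narrows candidates to `|v − v_measured| ≤ 0.03`.  Ties
break toward the lowest `Δa`, then lowest `v`.  Non-star-shaped
contours fall back to an arc-length curvature-signature distance and
are flagged.  Self-matches are exact, the metric is invariant to pose
and scale, and ≥90% of 2%-jittered renders match within one grid step.
Matched `Δa` values are a qualitative comparison, not a claim that the
observed vesicle physically has that leaflet-area difference.

## Problem sizes and runtime choices

The test suite and the acceptance script use a 0.05-step reduced
library (22 × 8 = 176 conditions, ~7 minutes), populations of 200–300
vesicles per condition (300 matching the per-condition sample size of
the emulated assay), five dose points, and 128–512 px frames.  These
sizes keep every statistical margin several standard errors wide while
the full run stays in the tens of minutes on one CPU.  The full
4400-condition library builds in a few hours and is exercised here
only through its grid arithmetic.

## Known limitations

* Only axisymmetric, star-shaped shapes are representable: deep
  stomatocytes and fully closed necks (fission) are out of reach and
  reported as non-converged.
* The solver returns the best converged local minimum of a
  deterministic multi-start family; no global-optimality certificate
  exists, and at geometrically infeasible grid cells the reported
  minimum can be a strained high-energy shape.
* Classifier thresholds (1% sphere, 5% fold, 15% neck, 0.8 pin/pear)
  are calibrated on the converged branch geometry of this model;
  by-eye taxonomies may name boundary cases differently.
* The synthetic generator's simplifications (above) bound what image
  -pipeline tests can claim about real micrographs.
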