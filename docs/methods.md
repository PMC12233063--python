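# Methods

`hexeye` segments every visible ommatidium in a 2D image of a *Drosophila*
compound eye and derives morphometrics from the result. This note describes
the models and procedures the package implements, the choices made where
the design was open, and what the synthetic benchmark does and does not
demonstrate.

## Pipeline overview

1. **Focus stacking** (`imageprep`). Brightfield eyes are strongly curved,
   so acquisition produces a Z stack (fixed step, 8 µm by default). Per
   pixel, the plane of best focus is the argmax of a local sharpness score —
   the variance of the Laplacian in a square window (default 9 px), a
   standard depth-from-focus metric. The argmax map is median-filtered with
   the same window (neighborhood voting suppresses speckle) before the
   all-in-focus composite is assembled. The chosen plane index, multiplied
   by the Z step and referenced to the lowest plane, is the pixel's
   physical altitude. RGB input is converted to luminance with ITU-R 601
   weights; integer intensities are rescaled to [0, 1] by the dtype
   maximum. Pixel coordinates are 0-based, x = column, origin top-left,
   everywhere in the package.

2. **Pixel classification** (`classify`). Two random forests of 100 trees
   each (scikit-learn, `min_samples_leaf=2`, library defaults otherwise;
   the tree count follows the established protocol for this task) are
   trained from sparse manual annotations: a closed outline of the eye
   region, and interior masks for a modest sample of ommatidia (~10–20% of
   a single eye suffices). The eye model separates inside/outside the
   outline; the facet model separates ommatidium interiors from boundary
   pixels, the latter derived as the morphological gradient (3-px element)
   of the annotated masks, since annotators mark facets, not boundaries.
   Features are a deterministic multi-scale filter bank: raw intensity
   plus, at σ ∈ {1, 2, 4, 8, 16} px, Gaussian blur, gradient magnitude,
   Laplacian of Gaussian, both Hessian eigenvalues, and local variance (31
   channels). Each class is subsampled to at most 50,000 pixels with a
   seeded generator, bounding training time and making runs reproducible.
   Applied to an image, the models yield the eye probability map and the
   facet probability map `I_prob`. The binary eye region is the Otsu
   threshold of the eye probability map (256-bin histogram, threshold at
   the bin edge maximizing between-class variance, implemented with
   cumulative moments), followed by largest-connected-component selection
   and hole filling — the cleanup prevents boundary over-detection on
   low-contrast (e.g. unpigmented) eyes from spawning satellite regions.

3. **Hexagonal-grid expansion** (`hexgrid`). Each ommatidium carries an
   integer axial coordinate `(x_hex, y_hex)` (six neighbors, offsets
   (±1,0), (0,±1), (1,−1), (−1,1)) and a continuous image position. The
   grid is seeded from three mutually adjacent facets at the eye center —
   supplied explicitly or found automatically as the three mutually closest
   thresholded-blob centroids nearest the eye centroid — with coordinates
   (0,0), (1,0), (0,1). Growth proceeds one facet at a time. Every
   registered mutually adjacent triplet (omtd1, omtd2, omtd3) predicts a
   fourth facet by point reflection of omtd1 through the omtd2–omtd3
   midpoint: `hex4 = hex2 + hex3 − hex1`, `pos4 = pos2 + pos3 − pos1`. The
   prediction is refined by fitting the three-circle "Mickey" template to
   the facet probability map: an m×m image of three filled circles of
   radius 0.225·m whose centers form an equilateral triangle of side 0.5·m,
   smoothed with a Gaussian of σ = m/20; pixels outside the circles dilated
   by 0.05·m are NaN and never scored, so surrounding facets cannot
   interfere. The two known neighbors anchor the "ears", the candidate the
   "face". For a candidate face position the affine map sending the
   template anchors onto (ear1, ear2, candidate) is applied to every scored
   pixel and the objective is

       Δ(x4, y4) = Σ (I_prob(A(i,j)) − θ·I_mouse(i,j))²,

   with the brightness factor solved in closed form (the objective is
   quadratic in θ: θ* = Σp·t / Σt²). Candidates are scanned on the integer
   pixel grid in a disk of radius 0.3·L_grid around the prediction —
   fits farther than that are rejected outright, so a wider search is
   pointless — followed by parabolic sub-pixel refinement. `L_grid`, the
   running mean distance over all registered adjacent pairs, is recomputed
   after every acceptance (the global form; a locally windowed variant
   would adapt faster at the rim but makes the acceptance radius depend on
   frontier order).

   Additional rejection constraints preserve grid integrity: the apparent
   facet tilt, computed from the singular values of the affine's linear
   part as arccos(s_min/s_max), must stay below 70° from normal view (a
   facet seen less than 20° from grazing cannot be localized reliably) and
   within 30° of omtd1's tilt (facet orientation changes gradually across
   the eye); and the mean probability under the face circle must be at
   least 0.25 of the mean under the ears. The last constraint closes a
   degeneracy of the masked squared error: over a blank map region θ → 0
   drives Δ → 0 with no facet present, because θ is carried by the ears
   (which sit on real facets). Without it, a ring of phantom facets forms
   in any margin between the outermost facets and the eye-mask edge; the
   measured separation on noise-free maps (face/ear mass ≈ 1 for real
   facets vs ≈ 0 for blank fits) makes 0.25 an uncritical choice.

   Expansion is best-first: all admissible candidate fits live in a
   priority queue on Δ (ties broken by hex coordinate, then insertion
   order); the best is accepted if it lies within L_grid/2 of its
   prediction, its face center falls inside the eye mask, and it is no
   closer than L_grid/2 to any registered facet; acceptance spawns fits for
   the new triplets it forms. The template side is tied to the grid,
   m = round(2·L_grid) (so the circle radius ≈ 0.45·L_grid matches the
   facet radius), with a floor of m = 20. The queue empties in finite time,
   so expansion always terminates; the whole procedure is deterministic.

   Manual correction is programmatic (no GUI): `remove` deletes by hex
   coordinate; `add_manual` registers a position and infers its hex
   coordinate as the unoccupied mirror slot predicting nearest to it,
   falling back to the nearest facet's open neighbor slot under a local
   least-squares lattice frame.

4. **Morphometrics** (`analysis`). Altitude is sampled at each facet's
   rounded position; with positions scaled to µm, the mean 3D Euclidean
   distance from each facet to its hex neighbors proxies the facet
   diameter (adjacent lenses are juxtaposed). Scattered values are smoothed
   by a least-squares bivariate polynomial (degree 3 by default — enough
   for a single-peak contour map without chasing noise; positions are
   normalized to [−1, 1] for conditioning), rasterized, and the in-mask
   argmax marks the enlarged-ommatidia zone. For column analysis the hex
   origin moves to the facet nearest the positional centroid and one of the
   12 lattice symmetries (signed axis permutations preserving the neighbor
   set) is applied so the most anterior facet — the one farthest along a
   user-supplied anterior direction, an acquisition convention the image
   cannot reveal — has positive coordinates; ties are broken
   deterministically by maximizing its column index, then x. The column
   index `x_hex + y_hex` then increases posterior → anterior, tracking the
   birth order of R8 founder cells behind the morphogenetic furrow. Column
   profiles (facets per column) from several eyes are aligned by integer
   shifts minimizing the squared difference to the running mean, iterated
   to convergence with the first profile anchoring the frame. Cross-eye
   spacing maps pool measurements by hex coordinate, keep coordinates
   present in at least half the eyes (rim coordinates vary between
   individuals and would dominate otherwise), and project the means onto a
   reference eye.

## The synthetic benchmark

`synthfly` generates eyes with exact ground truth. A uniform axial lattice
(apex spacing 16 µm — the *Drosophila* facet scale) is laid out in surface
(azimuthal-equidistant) coordinates, wrapped onto a spherical cap (polar
angle = surface radius / sphere radius) and orthographically projected;
orthographic projection matches long-working-distance SEM/macroscope optics
and keeps the ground truth closed-form. The sphere radius is derived from
the target facet count by equating the planar patch area with count × cell
area. Radial spacing is foreshortened by cos(θ) toward the rim, so facets
appear denser there, as in real images. The default cap half-angle is 60°:
the reliably visible part of the eye — facets seen closer to grazing are
ambiguous even to a human counter, and the generator additionally drops
facets steeper than 75°. Altitude follows the cap geometry; the facet
nearest the apex defines z by the cap height above the rim.

Rendering adds the photometric structure the classifier must cope with:
dome shading per facet with a dark boundary network (from first and second
nearest-center distances), specular highlights offset along the projected
surface normal, dark bristle segments rooted at alternating lattice
vertices ((i−j) mod 3 = 0, mimicking the real inter-ommatidial bristle
pattern), textured background, additive Gaussian noise, and, for stacks,
per-plane defocus interpolated between precomputed blur levels in
proportion to |facet altitude − plane altitude|. Ideal (noise-free)
probability maps — smoothed indicators of facet interiors and of the eye
mask — let the grid expansion be tested in isolation from the classifier.

A zone of enlarged ommatidia is planted by warping the planar lattice
radially about a center offset toward anterior-ventral: points move along
the integrated magnification ρ(r) = ∫(1 + A·e^(−t²/2w²))dt, so local
spacing acquires a smooth maximum of relative amplitude A (default 0.2,
matching the ~20% spacing variation observed across real eyes; center at
0.45 and width 0.45 of the patch radius). The observable ground-truth
location of the zone is not the warp center: the measured quantity is the
3D neighbor distance, whose baseline declines gently toward the rim
(azimuthal distances carry the metric factor sin θ/θ of the
azimuthal-equidistant layout), and because the planted bump is flat at its
top this shifts the field maximum slightly apex-ward. The generator
therefore reports the argmax of the closed-form composed field (warp
Jacobian × wrap metric, direction-averaged) as `zone_center`, and the
localization benchmark measures against that.

**What passing the synthetic benchmark shows — and what it does not.** The
generator reproduces the geometric structure the segmenter relies on
(hexagonal topology, curvature-driven density change, boundary/interior
contrast, bristles, defocus) but not everything real micrographs contain:
no damaged or fused facets, no lattice dislocations, no global illumination
gradients, no crescent-shaped rim facets, and the bristle/reflection models
are stylized. Perfect recovery on ideal maps validates the expansion
algebra and its rejection constraints; the rendered-image benchmark
additionally validates the classifier features on this texture family.
Accuracy on real images of a new modality still requires a small
annotation set and visual review of the result, which is why the
correction API exists.

## Numerical choices and degenerate inputs

- Otsu thresholding requires at least two occupied histogram bins;
  constant input is an error. When two splits tie in between-class
  variance to floating precision, either may be returned (the tests treat
  numerically tied splits as equivalent maximizers).
- Seed triplets must be distinct, mutually close (largest pairwise
  distance ≤ 3× the smallest) and non-collinear (relative area test,
  1e-9).
- The affine anchor solve rejects collinear targets by the same area test;
  template pixels are mapped through cached barycentric coordinates, so
  per-candidate evaluation needs no linear solves.
- Probability lookups outside the image evaluate to 0 (a candidate whose
  template falls entirely outside the image is an error).
- `fit_surface` requires more points than coefficients and a full-rank
  design; sub-pixel refinement is clipped to ±0.5 px and kept only if it
  does not increase Δ.
- Grid CSV round-trips are exact: floats are written with 17 significant
  digits and parsed with pandas' `round_trip` converter.
- Determinism: all stochastic steps (training subsampling, forest
  construction, generator) flow from explicit seeds; expansion order is a
  deterministic queue. Reruns are byte-identical.

## Problem sizes used in the shipped benchmarks

The test-suite and the reproduction script generate eyes of 600, 800 and
1500 facets — spanning the natural range for *Drosophila* — for the
ideal-map segmentation checks; the classifier end-to-end check trains on
one rendered 800-facet eye (150 annotated facets, the regime a user would
follow) and segments a second; the planted-zone check uses 20 replicates
of an 800-facet eye. These sizes exercise every code path at full realism
while keeping a complete run of the suite in the minutes range on one
core.

## Known limitations

- Interactive correction is deliberately out of scope; corrections are
  batch operations on the grid CSV.
- Eyes with severe structural abnormalities (fused or missing facet
  fields) violate the hexagonal-topology assumption and will not be
  segmented correctly.
- The altitude of a facet is the best-focus plane of its brightest
  structure, quantized to the Z step; rim facets seen near grazing have
  unreliable altitude and hence unreliable 3D spacing (flagged, not
  excluded, in the spacing map).
- The label image's per-pixel assignment floods a Euclidean
  distance-to-center map within the eye mask; for strongly non-convex
  masks this approximates, rather than equals, a geodesic Voronoi
  partition.
- Weka-format models are not read; classifiers are trained in-package.
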