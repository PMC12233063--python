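# hexeye

Complete segmentation and morphometrics of ommatidia in 2D images of
*Drosophila* compound eyes.

Fruit-fly eye size — the number and diameter of the ~600–1500 facets
(ommatidia) per eye — is a workhorse trait in evolutionary, developmental
and biomedical genetics, but counting every facet in a micrograph by hand
is slow enough to bottleneck large studies. `hexeye` automates it for SEM
images and multifocal brightfield stacks, for researchers who need
per-facet resolution: total counts, counts per anterior–posterior column,
and maps of facet diameter across the eye (the read-out used to locate
acute zones of enlarged ommatidia).

## Method

The pipeline has two phases. A machine-learning phase turns a focused 2D
image into probability maps: two 100-tree random-forest pixel classifiers,
trained from sparse annotations (the eye outline and ~100–150 manually
delineated facets), produce an eye-region map and a facet map
*I*<sub>prob</sub>; the binary eye region is the Otsu threshold of the
former. A hard-coded phase then exploits the crystalline hexagonal packing
of the eye. Every facet gets an integer lattice coordinate
(*x*<sub>hex</sub>, *y*<sub>hex</sub>) with six neighbors, and the grid
grows from a central seed triplet one facet at a time: a registered
triplet predicts a fourth facet by point reflection,

&nbsp;&nbsp;&nbsp;&nbsp;hex₄ = hex₂ + hex₃ − hex₁,&nbsp;&nbsp;
pos₄ = pos₂ + pos₃ − pos₁,

and the prediction is refined by fitting a three-circle template (two
"ears" on the known neighbors, one "face" on the candidate) to
*I*<sub>prob</sub>, minimizing Δ = Σ(*I*<sub>prob</sub>(A(i,j)) −
θ·*I*<sub>mouse</sub>(i,j))² over an affine pose A with a closed-form
brightness factor θ. Because each facet is placed relative to its
immediate neighbors, the segmentation adapts to the local spacing and
orientation changes that eye curvature imposes, including the compressed
rim where fixed-spacing (Fourier) detectors struggle. Fits that stray from
their prediction, tilt implausibly, or sit on blank map regions are
rejected; candidates outside the eye region are never added.

From multifocal stacks, depth-from-focus assigns each facet an altitude,
and the mean 3D distance to its six neighbors proxies its diameter; a
polynomial surface fit maps diameter across the eye and locates the
enlarged-facet zone. Column indices (*x*<sub>hex</sub> + *y*<sub>hex</sub>
after recentering and reorientation) reproduce the birth order of
ommatidial columns along the anterior–posterior axis.

A synthetic-eye generator (`hexeye.synthfly`) produces ground-truthed
images — hexagonal lattices on spherical caps with foreshortening, lens
shading, bristles, specular reflections and focal stacks — so every stage
of the pipeline is testable without microscopy data. See
`docs/methods.md` for the full model description.

## Worked example

Segment a synthetic 800-facet eye from its (noise-free) probability maps
and compute the morphometrics:

```python
import numpy as np
from scipy.spatial import cKDTree
from hexeye import (SyntheticEyeSpec, generate_lattice, ideal_probability_maps,
                    auto_seed, expand_grid, grid_edge_length, assign_altitude,
                    recenter_and_orient, column_profile, spacing_per_ommatidium,
                    count)

spec = SyntheticEyeSpec(n_target=800, seed=1)
gt = generate_lattice(spec)
maps = ideal_probability_maps(gt, spec)

grid = auto_seed(maps)            # three adjacent facets at the eye center
expand_grid(grid, maps)           # grow until no admissible facet remains
print(f"registered {len(grid)} ommatidia (ground truth: {gt.n})")
print(f"L_grid = {grid_edge_length(grid):.2f} px")

# altitude from the generator geometry (a focus stack provides this for real data)
ys, xs = np.mgrid[0:gt.shape[0], 0:gt.shape[1]]
_, near = cKDTree(gt.centers).query(np.column_stack([xs.ravel(), ys.ravel()]))
assign_altitude(grid, gt.z[near].reshape(gt.shape), px_size=spec.px_size)

reindexed = recenter_and_orient(grid, "right")   # anterior points right
total, n_cols = count(reindexed)
profile = column_profile(reindexed)
print(f"{total} ommatidia in {n_cols} columns")
print(f"largest column holds {profile.counts.max()} ommatidia")
spacing = spacing_per_ommatidium(reindexed)
print(f"mean inter-ommatidial distance: {np.mean(spacing.values):.1f} um")
```

This prints:

```
registered 805 ommatidia (ground truth: 805)
L_grid = 10.07 px
805 ommatidia in 35 columns
largest column holds 30 ommatidia
mean inter-ommatidial distance: 15.3 um
```

Every ground-truth facet is recovered, none twice, none outside the eye;
the mean 3D spacing (15.3 µm) sits just under the generator's 16 µm apex
spacing because rim facets are slightly compressed. The same flow runs on
real data via the CLI:

```
hexeye focus --z-step 8 stack.tif eye            # all-in-focus image + altitude
hexeye train --seed 0 annotations/ model.joblib  # from sparse label images
hexeye classify model.joblib eye_focused.tif eye # probability maps + mask
hexeye segment --auto-seed eye out               # grid CSV + label image
hexeye correct --add 512.3,401.8 out_grid.csv    # scripted review
hexeye analyze --px-size 1.33 --anterior right --altitude eye_altitude.tif \
    out_grid.csv analysis/                       # columns, spacing maps
```

`hexeye simulate` writes a full synthetic dataset (image or stack, ground
truth CSV, ideal maps) for benchmarking, and `hexeye run` chains all
stages from a JSON config.

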