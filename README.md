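# anatlayout

Anatomically anchored 2D sensor layouts for on-scalp arrays (OP-MEG, EEG,
or any digitised sensor set).

Conventional polar (azimuthal) projection flattens a sensor array about its
own geometric axis, so a channel's 2D position depends on head shape, head
position, and on *which other channels are present* — a real problem for
bespoke, sparse, or focal OPM arrays. `anatlayout` instead digitally
reconstructs the 10–20 reference frame on each individual's digitised head
shape and maps every sensor independently:

1. **Convex scalp hull** from head points + fiducials (NAS, INI, LPA, RPA);
   the head origin is the LPA–RPA midpoint.
2. **Plane-section tape measure**: the on-scalp distance between two surface
   points is measured along the intersection of the mesh with the plane
   through both points and the origin.
3. **10–20 frame**: the vertex Cz is found iteratively until it is
   equidistant (along the scalp, to 1 mm) from NAS/INI and LPA/RPA;
   landmarks FPz, T3, Oz, T4 sit at 80% of the Cz→fiducial arcs and are
   joined into the head-circumference path.
4. **Projection**: each sensor is ray-cast to the scalp; its 2D radius is
   the ratio of the on-scalp Cz→sensor and Cz→circumference distances in
   the same measurement plane (ratios > 1 plot outside the head circle),
   and its 2D angle interpolates the crossing point between bracketing
   landmarks (T4 = 0°, FPz = 90°, T3 = 180°, Oz = 270°, nose up).

Because every channel is located independently against anatomy, layouts are
exactly subset-independent and invariant to rigid motion and uniform
scaling — so per-subject topographies can be averaged and tested across a
group without warping the data.

The package also ships a polar-projection baseline, a group-statistics
pipeline (Delaunay-linear topographic interpolation, within-subject
z-scoring, pixelwise one-sample t-maps, sparse/focal channel subselection),
and synthetic-geometry generators (jittered ellipsoid heads, Fibonacci
sensor arrays, Gaussian-of-arc-distance sensitivity fields) used by the
tests and evaluation experiments.

## CLI

```sh
# make a synthetic head/fiducials/sensors dataset
anatlayout simulate --n-points 2000 --n-sensors 56 --seed 1 --outdir data/

# anatomical layout (FieldTrip-style .lay or JSON)
anatlayout layout data/head.txt data/fiducials.json data/sensors.tsv \
    --method anatomical --out layout.lay

# polar baseline from sensors alone
anatlayout polar data/sensors.tsv --out polar.lay

# group-statistics comparison from a JSON config
anatlayout compare config.json

# render a layout, optionally with per-channel values
anatlayout plot layout.lay --values values.csv --out topo.png
```

Exit codes: 0 success, 2 usage, 3 input-format error, 4 geometry failure.
If INI was not digitised it is estimated from the other three fiducials
(logged as a warning; documented approximation).

A `compare` config looks like:

```json
{
  "seed": 1, "n_subjects": 8, "n_sensors": 56,
  "n_keep": [56, 48, 40, 32, 24, 16],
  "modes": ["sparse", "focal"],
  "out_csv": "comparison.csv", "plot": "curves.png"
}
```

## Layout file formats

* `.lay`: `index x y width height label`, one row per channel, 6 decimal
  places, LF line endings.
* JSON: eccentricity / angle / x / y per channel plus outline metadata
  (unit circle, nose at 90°, ears at 0°/180°).

## Notable conventions

* Millimetres everywhere; inputs that look like metres are rejected rather
  than silently converted.
* On-scalp distances default to the shorter arc of the section loop, like a
  tape measure.
* z-scoring uses the population standard deviation; group t-maps use the
  sample standard deviation (one-sample t). The comparison summary reports
  mean |t| over valid pixels (a signed-mean switch is available).
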