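# Methods

## Scope and conventions

The package processes top-view LiDAR scans of maize breeding plots into
per-plant traits. Internal units are centimetres everywhere (sphere target
sizes given in millimetres are converted on input); the coordinate frame is
right-handed with Z up, and after leveling the soil plane is Z = 0. Point
clouds are read and written only in ASCII dialects (whitespace XYZ, ASCII
PLY, ASCII PCD v0.7) so fixtures and run artifacts stay bit-exact and
diffable; binary variants are rejected with a clear error rather than
half-parsed.

## Calibration

**Sphere targets.** Each calibration ball is fit with an algebraic linear
least-squares sphere (solving |p|² = 2c·p + r² − |c|²) followed by
Gauss–Newton refinement of the geometric distance (≤ 50 iterations,
tolerance 1e-10). The algebraic solve is exact on noiseless data; the
refinement makes partial coverage (a ball seen only from above) agree with
the true geometric least-squares optimum. The scale correction is the mean
over targets of known/fitted diameter. Because diameter-only targets cannot
fix a datum, the correction is applied by scaling coordinates about the
cloud centroid.

**DLT registration.** The 11-parameter model is used in the residual form
x + N_x/D = 0, y + N_y/D = 0 with D = l9·X + l10·Y + l11·Z + 1, i.e.
x = −N_x/D. The solver clears denominators, giving two linear equations per
correspondence, and solves by least squares. Image and object coordinates
are centred and isotropically scaled to RMS √2 / √3 before the solve and
the similarity transforms are undone afterwards — the standard conditioning
step, without which the normal equations are numerically fragile. At least
6 correspondences are required and the object points must span 3D: the
coplanar case leaves the model unobservable and is rejected via an SVD rank
check. Noise-free synthetic projections reproject to < 1e-8 px across
random cameras (tested over 20 seeds).

## Preprocessing

**Statistical outlier removal** computes each point's mean distance to its
k nearest neighbors (k-d tree) and removes points above the global mean
plus `std_ratio` standard deviations. Defaults k = 20, std_ratio = 2.0 —
common practice for LiDAR scenes; both are exposed in the pipeline config.

**Voxel down-sampling** replaces every occupied voxel with the centroid
("gravity center") of its members. Two conventions matter and are fixed
here: the grid origin is the minimum corner of the cloud's bounding box
(membership is then independent of the world datum), and voxel membership
is half-open by floor division, so a point exactly on an upper face belongs
to the higher-index voxel. Labels propagate by majority vote per voxel,
ties to the smallest id. The filter is checked against a brute-force
bucket-hash oracle. Grid lengths of 0.2 / 0.5 / 1 cm are the studied
operating points; 0.5 cm is the pipeline default. The compression summary
reports the plain percentage retained (100 × after/before) and nothing
else.

Pipeline order is outlier removal first, then down-sampling: stray returns
would otherwise contaminate voxel centroids.

## Ground handling

RANSAC plane fitting samples 3 points per iteration (default 1,000
iterations, seeded RNG), counts inliers within a signed-distance threshold
(default 1.0 cm), refits the winning plane by total least squares on its
inliers (smallest principal direction — removes the bias of a 3-point
plane) and refreshes the inlier set once. Normals are oriented with
positive Z. Leveling rotates the fitted normal onto +Z about their common
perpendicular and translates the plane to Z = 0; the transform is rigid, so
applying it twice (with a refit plane) is the identity to numerical
precision. Ground removal drops points with signed distance ≤ margin
(default 1.0 cm) — with margin 0 on noisy data some ground survives, which
is documented behavior, not an error. Near-ground clutter such as drip
lines is treated as generic points inside the margin rather than modeled
separately. The stage order is fit → level → remove; fitting before
leveling is required, and removing after leveling keeps the margin an
interpretable height above Z = 0.

## Segmentation

Points are assigned to breeding plots by half-open rectangle membership
([xmin, xmax) × [ymin, ymax)), so shared boundaries are unambiguous. Plant
instances are connected components of the voxel occupancy graph at
`cell_size` (default 5 cm, 26-neighbor adjacency) — single-linkage
Euclidean clustering that is deterministic and fast at desk scale. Clusters
under `min_points` (default 50) are discarded and counted. The stem base of
an instance is the XY median of its lowest Z-decile. A cluster spanning
more than 1.8× the expected plant spacing triggers a touching-canopy
warning: overlapping leaves are the known failure mode of geometric
separation, and this module is deliberately interface-compatible with a
learned instance segmenter that could replace it for closed canopies.

Instances that fit a sphere of plausible target size (diameter 5–50 cm,
RMS residual < 4% of radius) are excluded from phenotyping by the pipeline:
calibration balls sit above the soil and would otherwise be reported as
plants.

## Traits

**Plant height** is Zmax − Zmin over the instance's points. In the pipeline
the cloud is leveled, so the ground reference Z = 0 is passed and height is
measured as Zmax − 0: ground removal strips the lowest `margin` of each
stem, and measuring to the soil plane (which is how field height is
defined) avoids that margin-sized bias. Both behaviors are available in
`plant_height`.

**Leaf separation.** The stem axis is the vertical line through the XY
median of the densest vertical column (the XY bin with the largest Z
extent — leaves are locally flat, only the stem spans the full height).
Points within 2.5 cm (XY) of the axis are stem; the rest are clustered by
connectivity at 2 cm into leaves, which separates opposite leaves at equal
growth height azimuthally.

**Midrib and metrics.** Each leaf's points are ordered along their first
principal direction and averaged in transverse slices (one per cm, at
least 20), giving an ordered midrib polyline. The attachment point is the
polyline extrapolated back to the stem axis: height vs. radial distance is
fit with a quadratic over the basal vertices and evaluated at radius 0.
Leaf length is the polyline arc length from attachment to tip; leaf width
is the maximum transverse extent over slices (extent perpendicular to the
local tangent); growth height is the attachment Z. Leaf inclination θ is
the complement of the stem–leaf angle — the angle of the midrib's *base
tangent* above the horizontal, clamped to [0, 90]°. Because maize midribs
droop smoothly, the base tangent is taken as the derivative at radius 0 of
the same quadratic fit rather than a secant through basal vertices; a
secant systematically underestimates erect, arched leaves by several
degrees, while the quadratic is unbiased for a quadratically arched midrib.
The stem is assumed vertical after leveling (no lodging model).

## Evaluation

R² is computed exactly as 1 − Σ(v−v′)²/Σ(v−v̄)² (coefficient of
determination about the manual mean), RMSE as the root mean square of
paired differences, and relative errors as 100·|v−v′|/v with the manual
value as denominator. The squared Pearson correlation is reported alongside
because regression software labels that quantity R²; the two differ
whenever the system is biased, and on the bundled table they do (0.88 vs
0.91 for the first date). Statistics are rounded only at rendering time,
never during computation. The 30-pair plant-height validation table ships
as a CSV fixture guarded by a checksum test; it is the only real field data
available to the package.

## Synthetic canopy generator

The generator is the package's test bed and defines the conditions under
which the quantitative claims hold.

*What it emulates:* a gently sloped soil plane (default 2°) with Gaussian
micro-relief (σ 0.2 cm); maize plants on a regular grid (default 60 cm
spacing both ways with ±2 cm placement jitter, 2×3 plants) with a vertical
cylindrical stem (radius 1.2 cm) and 4 leaves per plant; the two
calibration balls (25 and 20 cm) tangent to the soil in bare corners;
isotropic Gaussian sensor noise (default σ 0.1 cm); and uniform box
outliers (default 30). Plant surfaces are sampled on a deterministic grid
at 4 points/cm² (LiDAR-like; keeps full scenes well under 10⁶ points), so
a seeded scene regenerates identically.

*Leaf model:* the midrib leaves the stem at the leaf's growth height along
its azimuth at the stated inclination and droops quadratically; the `arch`
coefficient is tip droop as a fraction of leaf length (default draw
0.10–0.25). The parameter range of the quadratic is solved numerically so
the midrib arc length equals the specified leaf length exactly. Blade width
tapers linearly from 0.4× the maximum at the base to the maximum at 1/3 of
the length, then to a sharp tip — a common maize idealization that makes
every reported trait analytically known. Random plants draw height from
N(80, 4) cm (jointing stage), growth heights spread over 0.15–0.85 of the
height with distichous (alternating ±180° ± 25°) azimuths, leaf length
0.21–0.29 of plant height, width 14–20% of length, inclination 20–45°;
inclinations are reduced if a leaf apex would exceed the stem top, keeping
the stem the highest point. The leaf-length fraction is chosen so that
plants on the default 60 cm grid remain separated by more than the 5 cm
clustering distance — the sparse, well-separated plot condition the
geometric segmenter is designed for.

Plants are grown along the local soil normal, so leveling restores the
canonical upright geometry exactly; at the few-degree slopes emulated the
difference from gravity-vertical growth is below measurement resolution.

*What it does not emulate:* occlusion and shadowing (every surface point is
visible), beam divergence and range-dependent noise, wind deformation,
radiometry/intensity, touching or interleaved canopies, lodged plants, and
real soil clutter (residue, drip lines). Passing the recovery tests
therefore demonstrates correctness of the geometry processing under clean
separability, not field-grade robustness of the segmentation — the known
gap, shared with the platform's own discussion of dense canopies, is
flagged by the touching-canopy warning.

## Problem sizes and numerical notes

Tests and the acceptance checks run on desk-scale scenes (1–6 plants,
~20k–60k points, ground sampled at 0.5–1 point/cm²) chosen so the full
suite completes in well under a minute while every stage still operates in
its intended regime; ground-plane tests use scenes with roughly 20%
non-ground points, matching the validated operating condition. Determinism
is enforced end to end: a pipeline config plus seed reproduces
byte-identical trait CSVs. Degenerate inputs are contracts, not crashes:
empty clouds are legal for I/O, single-point instances warn and report
height 0, leafless stems return an empty leaf list, coplanar DLT/sphere
configurations and collinear RANSAC samples raise informative errors.

## Known limitations

- Geometric instance segmentation fails on closed canopies (by design; the
  interface accepts a drop-in learned segmenter).
- Leaf width is the strip's maximum transverse extent; on strongly curled
  real leaves this underestimates the flattened botanical width.
- The DLT module covers registration only; camera intrinsics, lens
  distortion and bundle refinement are out of scope.
- The evaluation module treats the transcribed validation table as given;
  its printed R² values are reproducible only as the squared Pearson
  correlation of a regression fit, so this package reports both definitions
  explicitly rather than matching a single number.
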