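# canopy-pheno

Point-cloud processing for high-throughput field phenotyping of maize.
Track-mounted LiDAR platforms scan breeding plots from above and deliver
dense 3D point clouds; turning those into plant traits requires a chain of
geometric processing steps. This package implements that chain as a tested,
reusable library plus a small CLI:

1. **Calibration** — least-squares fitting of calibration balls of known
   diameter (250 mm and 200 mm targets) for scale verification, and
   11-parameter **direct linear transformation (DLT)** registration between
   2D image and 3D cloud coordinates:

   ```
   x + (l1 X + l2 Y + l3 Z + l4) / (l9 X + l10 Y + l11 Z + 1) = 0
   y + (l5 X + l6 Y + l7 Z + l8) / (l9 X + l10 Y + l11 Z + 1) = 0
   ```

2. **Preprocessing** — statistical outlier removal (k-nearest-neighbor mean
   distance thresholding) and voxel-grid down-sampling (each occupied voxel
   replaced by the gravity center of its points).
3. **Ground handling** — RANSAC soil-plane fitting, rigid leveling of the
   scene so the soil sits at Z = 0, and margin-based ground removal.
4. **Segmentation** — assignment of points to breeding plots from a plot
   map, and plant instance separation by Euclidean clustering on a voxel
   occupancy graph.
5. **Traits** — per plant: height (Zmax − Zmin), and per leaf: length
   (midrib arc length), width (maximum transverse extent), inclination θ
   (complement of the stem–leaf angle, i.e. the midrib base tangent's angle
   above the horizontal) and growth height (attachment height on the stem).
6. **Evaluation** — manual-vs-system agreement statistics:

   ```
   R²   = 1 − Σ (v_l − v'_l)² / Σ (v_l − v̄)²
   RMSE = sqrt( (1/m) Σ (v_l − v'_l)² )
   ```

   plus mean absolute error and per-item relative errors.

Because no public scan of a real field accompanies this work, the package
includes a fully ground-truthed **synthetic canopy generator** (sloped rough
soil, parametric maize plants, calibration spheres, sensor noise, outliers)
that every stage is validated against, and a transcribed 30-pair field
validation table of manually vs. system-measured plant heights.

All coordinates are centimetres; Z is up; after leveling the soil plane is
Z = 0.

## Worked example

Agreement statistics on the bundled field validation table:

```python
from canopy_pheno.evaluation import (
    load_plant_height_table, pairs_from_frame, evaluate_pairs,
)

table = load_plant_height_table()           # 30 manual/system height pairs
for pm in pairs_from_frame(table, ["date"]):
    rep = evaluate_pairs(pm)
    print(f"{pm.label}: m={rep.m}  RMSE={rep.rmse_cm:.2f} cm  "
          f"R2={rep.r2:.4f}  rel err max/min="
          f"{rep.max_rel_pct:.2f}/{rep.min_rel_pct:.2f} %")
```

prints

```
2020-08-14: m=15  RMSE=0.99 cm  R2=0.8774  rel err max/min=5.11/0.38 %
2020-08-27: m=15  RMSE=1.80 cm  R2=0.8650  rel err max/min=3.45/0.71 %
```

i.e. plant heights measured from the LiDAR cloud agree with manual ruler
measurements to about 1–2 cm RMSE on ~50–90 cm plants.

Full pipeline on a synthetic 6-plant scene, validated against the
generator's ground truth:

```python
from canopy_pheno.pipeline import PipelineConfig, run_pipeline, validate_against_truth

cfg = PipelineConfig(scene={"rows": 2, "plants_per_row": 3}, seed=42)
res = run_pipeline(cfg, "runs/demo")
print("counts:", res.counts)
for name, rep in validate_against_truth(res).items():
    print(f"{name}: m={rep.m}  RMSE={rep.rmse_cm:.2f}  MAE={rep.mae_cm:.2f}")
```

prints

```
counts: {'input': 60793, 'statistical_filter': 60761, 'voxel_downsample': 53692, 'ground_removed': 24797, 'instances': 6}
height_cm: m=6  RMSE=0.18  MAE=0.17
length_cm: m=24  RMSE=0.34  MAE=0.27
width_cm: m=24  RMSE=0.24  MAE=0.17
inclination_deg: m=24  RMSE=5.26  MAE=4.16
growth_height_cm: m=24  RMSE=0.29  MAE=0.24
```

All 6 plants are recovered; heights are within a few millimetres of truth
under the default 1 mm sensor noise, and leaf traits are recovered to
sub-centimetre RMSE (inclination to a few degrees).

The same chain is available from the shell:

```sh
canopy-pheno simulate --seed 5 --out sim/          # scene + ground truth
canopy-pheno run --config pipeline.yaml --out run/ --validate
canopy-pheno evaluate --pairs pairs.csv --group-by date,group
canopy-pheno fit-spheres ball1.xyz ball2.xyz --known 25,20
canopy-pheno dlt --correspondences cors.csv --out model.json
```

## Layout

```
src/canopy_pheno/
  cloud.py         PointCloud / PlotMap containers
  io.py            ASCII XYZ / PLY / PCD readers and writers
  synthetic.py     ground-truthed canopy scene generator
  calibration.py   sphere fitting, scale calibration, DLT
  preprocess.py    statistical outlier removal, voxel down-sampling
  ground.py        RANSAC plane, leveling, ground removal
  segmentation.py  plot assignment, plant instance clustering
  traits.py        plant height and leaf phenotypes
  evaluation.py    R² / RMSE / relative-error reports + bundled table
  pipeline.py      end-to-end orchestration
  cli.py           canopy-pheno command line
docs/methods.md    modelling and algorithmic notes
```
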