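# maizefusion

Multi-source fusion of LiDAR point clouds and orthorectified RGB images for
time-series structural phenotyping of field maize populations.

Field phenotyping platforms collect per-date LiDAR point clouds and top-view
orthomosaics of the same plots, but the two sensors live in different
coordinate frames and each date's cloud drifts relative to the last. Without
registration, per-plant traits cannot be tracked through the season, and once
the canopy closes, single-cloud segmentation scatters points of one plant into
its neighbors. `maizefusion` implements the full fusion pipeline:

1. **Image-cloud registration by direct linear transformation (DLT).**
   Vegetation is binarized with the excess-green index (2G − R − B, Otsu
   threshold); plant-silhouette centroids, contour samples and calibration
   markers become feature points; the cloud is parallel-projected and the same
   features extracted from its rendering. Matched (x, y) ↔ (X, Y, Z) pairs feed
   the 11-coefficient DLT

   x + (l₁X + l₂Y + l₃Z + l₄)/(l₉X + l₁₀Y + l₁₁Z + 1) = 0,
   y + (l₅X + l₆Y + l₇Z + l₈)/(l₉X + l₁₀Y + l₁₁Z + 1) = 0,

   linearized into the stacked system V = BL − W and solved by weighted least
   squares L = (BᵀPB)⁻¹BᵀPW. Six pairs are the solvability minimum (12
   equations, 11 unknowns); the operational gate defaults to 12 matched points.
   The fitted model yields the in-plane rotation, uniform scale and translation
   that bring each date's cloud into the reference image frame.
2. **Ground removal.** KD-tree statistical denoising, then the cloth
   simulation filter (CSF): the cloud is inverted (z → −z), a particle grid
   governed by m·∂²A/∂t² = F_ext(A,t) + F_int(A,t) drops under gravity, clamps
   where it meets the inverted surface, and relaxes its internal springs; points
   within a vertical threshold of the settled cloth are ground.
3. **Plant and organ segmentation.** Stem positions are density modes of the
   2D-projected point histogram (quickshift mode seeking: each cell links to
   its nearest higher-density cell; link-tree roots are seeds), plants grow
   from seed columns over a 3D proximity graph with a global minimum-gap
   priority frontier, and each plant splits into a stem column plus leaves
   clustered along the stem. In *guided* mode, a date's seeds are the previous
   date's stem positions carried through the registration — the fusion behavior
   that keeps plants separable in closed canopies.
4. **Traits and assessment.** Plant height (99th-percentile z above the local
   terrain), crown size (xy convex-hull area), leaf inclination and azimuth
   (midrib chord angles), leaf length (binned-midrib polyline); scored against
   reference tables with R² = 1 − Σ(vₗ−vₗ′)²/Σ(vₗ−v̄ₗ)², MSE, RMSE and MAE
   (azimuths compared with wrapped differences).

Because no field data ships with the package, a first-class synthetic-scene
generator (`maizefusion.synthetic_scene`) emulates the acquisition: maize rows
0.60 m apart, plants 0.30 m apart, parametric plants (logistic stem growth,
parabolic-arc leaf midribs with known angles and lengths), rough ground with
drip-tape ridges, white calibration squares, top-down occlusion, per-date
rigid+scale frame offsets, and ground-truth labels and traits computed from
the generative parameters.

## Worked example

```python
import maizefusion as mf
from maizefusion.pipeline import process_series

cfg = mf.FieldConfig(n_rows=2, plants_per_row=3, growth_stage=0.35,
                     point_density=2500, seed=1)
scenes = mf.make_time_series(cfg, n_dates=2)          # 2 acquisition dates
truth = scenes[0].traits.concat(scenes[1].traits)

traits, segs, report = process_series(scenes, seed=0, guided=True)
for entry in report:
    print(f"{entry['date_tag']}: {entry['status']}, "
          f"{entry['n_matches']} matched features, "
          f"rotation {entry['rotation_deg']:.2f} deg, "
          f"residual {entry['residual']*100:.1f} cm")

rep = mf.evaluate(truth, traits, "plant_height")
print(f"plant height: m={rep.m}  R2={rep.r_squared:.3f}  "
      f"RMSE={rep.rmse*100:.1f} cm  MAE={rep.mae*100:.1f} cm")
```

prints

```
d1: ok, 10 matched features, rotation -0.06 deg, residual 2.6 cm
d2: ok, 10 matched features, rotation -1.79 deg, residual 3.9 cm
plant height: m=12  R2=0.999  RMSE=0.5 cm  MAE=0.3 cm
```

Date 2 was generated with a hidden rigid+scale offset; the report shows the
rotation the registration applied to undo it and the residual distance between
matched image and cloud features after registration. The trait table is then
scored against the generative truth: 12 height records (6 plants × 2 dates)
recovered to half a centimeter.

The same pipeline is available from the shell:

```sh
maize-fusion simulate --rows 2 --plants 3 --stage 0.35 --dates 2 --seed 1 --out sim/
maize-fusion run --config pipeline.yaml        # register -> ground -> segment -> traits
maize-fusion benchmark --seed 0 --replicates 10  # guided vs. fresh segmentation
```

See `maize-fusion --help` for the per-stage subcommands (`features`,
`align-images`, `register`, `ground`, `segment`, `traits`, `evaluate`).

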