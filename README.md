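# ctoam — computed tomographic osteoabsorptiometry

`ctoam` maps the density of the subchondral bone plate onto the articular
surface of a joint from calibrated CT, and compares paired longitudinal
scans. It was built around the canine talus (the trochlear ridges of the
hock joint), where subchondral density reflects the joint's long-term
loading history and is expected to increase during growth, but the pipeline
is generic: it takes any CT volume with a bone mask.

The method, stage by stage:

1. **Calibration.** A density-reference phantom with inserts of known
   hydroxyapatite density is scanned with the subject. Ordinary least
   squares through the (mean ROI HU, nominal density) pairs gives the
   affine map `ρ [mg HA/cm³] = a·HU + b`, removing inter-scan variability.
2. **Surface-anchored MIP.** For each view (proximal; dorsal = proximal
   tilted backwards 90° about the medial–lateral axis) an orthographic ray
   is cast per pixel. Where the ray first enters the bone mask — the
   articular surface — a segment of depth 1.5 mm extends into the bone and
   the pixel records the maximum interpolated HU along it. The result is a
   2D *densitogram* of the subchondral bone plate.
3. **Quantization and density maxima.** Densitogram HU are converted to
   8-bit levels over a fixed 200–1200 HU window and split equally into 8
   bins (32 levels each). A *density maximum* is a connected region of
   pixels in the two highest bins. Maxima are localized on a 30 × 30 unit
   grid spanned by the joint surface's bounding box (size-normalized
   coordinates) and summarized by the maximum area ratio

   ```
   MAR = (pixels of the density maximum) / (pixels of the total joint surface)
   ```

4. **Paired statistics.** Per view, mean density, maximum density and MAR
   are compared between time points with a paired Student's t-test
   (normality of the differences checked by Shapiro–Wilk, α = .05); maxima
   displacements are tested per coordinate and jointly (Hotelling T²).

Because no real scans ship with the package, a seedable synthetic
generator (`ctoam.synthetic`) renders trochlea-like volumes — two
partial-cylinder ridges with a dense subchondral shell, Gaussian density
hotspots, phantom inserts, and additive HU noise — with full ground truth,
so every stage is testable end to end.

## Worked example

Simulate a 10-subject paired cohort (densities ×1.15 at the second scan,
fixed hotspot anchors, 5 HU noise) and run the whole chain:

```python
from dataclasses import replace
from ctoam.pipeline import RunConfig, run_pipeline
from ctoam.synthetic import default_spec

config = RunConfig(n_subjects=10, growth_factor=1.15, seed=20170220,
                   spec=replace(default_spec(), noise_sd=5.0))
result = run_pipeline(config)
print(result.comparison.table[["view", "metric", "t1_mean", "t1_sd",
                               "t2_mean", "t2_sd", "p_value"]])
```

which prints (densities in mg HA/cm³, MAR in %, mean (SD) over 10 subjects):

```
    view       metric           t1            t2      p_value
  dorsal mean_density 607.6 (29.3)  698.5 (33.9) 3.148333e-13
  dorsal  max_density 896.9 (42.8) 1031.1 (49.4) 5.186044e-12
  dorsal      mar_pct    8.6 (3.1)    20.0 (4.9) 1.055865e-08
proximal mean_density 576.6 (27.9)  663.0 (32.2) 2.843080e-13
proximal  max_density 896.9 (42.8) 1031.1 (49.4) 5.186044e-12
proximal      mar_pct    3.5 (1.2)     8.3 (2.0) 1.435331e-08
```

Mean density, maximum density and MAR all increase significantly between
the two scans, while the maxima *locations* do not move
(`result.comparison.coordinates`: Hotelling p = .92 proximal, .41 dorsal) —
the density scale grows but the loading pattern stays put, which is exactly
the behaviour the generator encodes.

The same study is available as narrative drivers: `analysis/01` simulates
the cohort, `02` checks calibration recovery, `03` maps densitograms and
per-joint metrics, `04` runs the longitudinal comparison; tables land in
`results/`. A CLI mirrors the stages
(`ctoam simulate|calibrate|project|quantify|compare|run`), e.g.

```sh
ctoam simulate --out sim/ --seed 5
ctoam quantify --volume sim/volume.nii.gz --mask sim/mask.nii.gz \
               --view proximal --out maxima.json
```

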