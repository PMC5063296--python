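# phantex

Phantom-based quality assurance for PET texture heterogeneity parameters.

Texture ("radiomics") indices computed on FDG-PET tumour volumes are widely
proposed as biomarkers, but many of them are confounded by the delineated
volume, by acquisition/reconstruction settings, or simply do not respond to
genuine changes in uptake heterogeneity. `phantex` implements a
phantom-based selection protocol for deciding which of 27 common
heterogeneity parameters are worth using clinically, entirely with
simulated phantom acquisitions:

1. **Volume independence.** A homogeneous 20 cm cylinder (5 kBq/ml F-18) is
   imaged on three reconstruction protocols; each parameter is evaluated on
   concentric spherical VOIs from 0.5 to 1000 ml and its log–log curve above
   30 ml is classified as converging (A), positive slope (B), random-like
   (C) or negative slope (D).
2. **Reproducibility.** A 7-syringe "Revolver" insert (8.66 mm bores, 3 ml
   each; 20/40/80 kBq/ml over a 5 kBq/ml background) inside a NEMA-IQ-like
   body is imaged in triplicate for every combination of 6 reconstruction
   settings × 4 acquisition times (60–240 s); the replicate coefficient of
   variation CV = SD/mean per cell must stay below 10% in (almost) all
   cells.
3. **Sensitivity.** The insert is filled with a C-11 / F-18 mixture and
   imaged dynamically for 80 min: differential decay sweeps the pattern
   from heterogeneous through homogeneous (where decay-corrected
   activities cross) and back. A parameter must change by at least 20%
   relative to its homogeneous-frame value.

A parameter is *selected* only if it passes all three criteria.

## The 27 parameters

Voxel values inside the VOI are resampled to 64 grey levels,

&nbsp;&nbsp;&nbsp;&nbsp;V(x) = ⌊ 2^S · (I(x) − min I) / (max I − min I) + 1 ⌋,&nbsp;&nbsp;2^S = 64,

and three volumetric texture matrices are built inside the mask only:
the grey-level co-occurrence matrix (GLCM; symmetric pair probabilities
averaged over the 26 neighbour directions), the run-length matrix (GLRLM;
maximal collinear runs over the 13 unique 3D directions) and the size-zone
matrix (GLSZM; 26-connected constant-grey zones). From these come
Homogeneity, Correlation, Entropy, Contrast, Intensity Variability, 10
run-length and 11 size-zone statistics; the Coefficient of Variation
(sample SD over mean of the raw intensities) completes the 27.

## Worked example

```python
from phantex import (build_revolver_phantom, reconstruction_setting,
                     simulate_pet_image, threshold_segment, compute_all_features)

amap = build_revolver_phantom([80, 40, 40, 20, 20, 20, 5])   # kBq/ml
setting = reconstruction_setting("A", acq_time_s=120, seed=7)
img = simulate_pet_image(amap, setting)
voi = threshold_segment(img, mode="relative", threshold=2.5)  # > 2.5 x background
fv = compute_all_features(img, voi, n_levels=64)
print(f"VOI volume: {fv.volume_ml:.1f} ml")
for p in ("ENT", "CON", "COR", "HOM", "CoV"):
    print(f"{p:>4}: {fv[p]:.4f}")
```

prints

```
VOI volume: 27.6 ml
 ENT: 9.9089
 CON: 365.8063
 COR: 0.3961
 HOM: 0.2149
 CoV: 0.4183
```

The segmented insert (~28 ml after blurring) carries a strongly
heterogeneous pattern: entropy near 10 bits and a CoV of 0.42 reflect the
three distinct syringe activity levels plus noise, while the moderate
correlation (0.40) reflects the smooth point-spread structure.

The full study runs from the command line:

```bash
phantex run-all --config configs/study.yaml --out out/
```

which writes the volume curves, the CV grid, the sensitivity profiles and a
JSON selection report listing the per-criterion verdicts for all 27
parameters and the final selected set.

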