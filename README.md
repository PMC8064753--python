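# granulekit

Quantification of RNP-granule remodeling in confocal microscopy of
neuronal cell bodies. `granulekit` is for cell biologists who measure how
membrane-less ribonucleoprotein (RNP) condensates respond to stimuli —
decondensation of granule proteins, release of granule-associated RNAs,
accompanying calcium signals and translation bursts — from single-plane
fluorescence images and time-lapse movies.

## What it computes

The central statistic is the **partition coefficient** of a granule
component,

```
PC_i = max(I_raw over granule i) / mean(I_raw over cytoplasm mask)
```

the ratio of a protein's intensity inside an individual granule to its
diffuse cytoplasmic pool (PC → 1 means fully decondensed). Granules are
detected as puncta on a ×2-upsampled, smoothed detection grid using a
scale-normalized Laplacian-of-Gaussian band-pass with curvature-based
edge rejection, thresholded at a unitless fraction of the in-image
response range; the threshold is calibrated by maximizing the F1 score
against point annotations. The cytoplasm mask blanks granule footprints,
blurs with σ = 8 px, and keeps pixels above the global blurred mean.

Around the partition coefficient, the package provides:

- **synthgen** — synthetic confocal fields, smFISH channel pairs,
  decondensation time-lapses ρ(t) = ρ_f + (ρ_0 − ρ_f)·e^(−k·t), and
  calcium traces, all with complete ground truth;
- **detect** — preprocessing, particle detection, size filters (4-px
  minimum, optional 13-px antibody-channel exclusion), raw-image
  intensity measurement, F1 scoring and threshold calibration;
- **partition** — cytoplasm masks, per-field coefficients, per-frame
  time-lapse means, exponential-relaxation fits, protein-level controls;
- **coloc** — object-based colocalization: the fraction of RNA-spot
  centers of mass contained in granule particles, with control
  normalization;
- **traces** — GCaMP ΔF/F with a 4-frame baseline, dose–response
  endpoints normalized to t0, per-movie-max foci normalization, fixed-ROI
  reporter intensities on max projections;
- **reportstats** — control normalization, SuperPlot summaries
  (replicate means vs pooled means), Welch t / Mann–Whitney /
  Kruskal–Wallis + Dunn / ANOVA + Dunnett, and the ≥10-peptide,
  ≥2×-enrichment, both-replicates co-IP interactor filter.

## Worked example

```python
from dataclasses import replace
import granulekit as gk

# a synthetic field: 25 granules in packed somata, known ground truth
spec = gk.random_scene(n_granules=25, seed=3)
field, truth = gk.generate_field(spec, seed=3)

# calibrate the detection threshold by F1 against the true centers
grid = [round(0.10 + 0.02 * i, 2) for i in range(41)]
cal = gk.calibrate_threshold([field], [[g.center for g in truth.granules]], grid)
params = replace(gk.GRANULE_PARAMS, relative_threshold=cal.best_threshold)

granules, result = gk.quantify_field(field, params)
print(f"threshold {cal.best_threshold:.2f}  "
      f"granules {result.n_granules}  "
      f"mean PC {result.field_mean:.3f}  "
      f"true mean PC {truth.true_partitions().mean():.3f}")
```

prints

```
threshold 0.30  granules 25  mean PC 2.581  true mean PC 2.579
```

— the F1-optimal threshold detects all 25 granules, and the measured
mean partition coefficient agrees with the generator's ground truth to
about 0.1% (the residual comes from mask edges and preprocessing blur).

The same objects drive the command line:

```bash
granulekit simulate field --n-granules 25 --seed 3 --out scene/
granulekit detect --in scene/field.tif --out scene/granules --threshold 0.30
granulekit partition --movie scene/field.tif --out scene/ --threshold 0.30
```

## Documentation

`docs/methods.md` describes the scene model, the detector and its
relation to the published SPaDe interface, the cytoplasm-mask geometry
requirement, all defaults with units, and known limitations.
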