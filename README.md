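# spectquant

Quantitative analysis of cardiac SPECT/CT uptake volumes:

* **SUV quantification** — decay correction to injection time and
  normalisation by injected dose per kilogram body weight. No
  camera/well-counter cross-calibration is applied, so all uptake values are
  in arbitrary but internally consistent units.
* **Isocontour segmentation** — per-VOI threshold at a configurable fraction
  (default 42 %) of the VOI maximum, with inclusive comparison so the
  maximum voxel is always retained.
* **Per-region metrics** — mean and max uptake over the segmented set, the
  segmented volume in mL, and the compound burden score
  `burden = mean_uptake × segmented_volume_ml`.
* **Region model** — four base walls (LV lateral wall, interventricular
  septum, apex, RV free wall) plus a sternum mask; merged `LV` and
  `VENTRICLES` regions; a distance-based sternum spill-over exclusion for
  the RV free wall (default border 10 mm).
* **Apical-sparing ratios** — uptake variant `apex / mean(IVS, lateral)`
  (no cut-off) and strain variant `apical / (basal + mid)` with a strict
  cut-off of 1.
* **Reorientation** — rigid resampling of a transaxial volume/mask pair into
  cardiac short-axis orientation from explicit rotation angles (trilinear
  for intensity, nearest-neighbour for labels).
* **Synthetic data** — a digital cardiac phantom (ellipsoidal LV shell with
  lateral/septal/apical sectors, RV crescent, hot sternum bar, Gaussian PSF
  as partial-volume surrogate, optional Poisson noise) with ground-truth
  masks, and a synthetic 48-subject cohort with tunable correlation
  structure between uptake metrics, strain and biomarkers.
* **Cohort statistics** — Pearson correlations with two-tailed t-test
  p-values (complete-case per pair), base-10 biomarker log transform,
  Kruskal–Wallis with mid-rank tie correction, correlation-report assembly
  and apical-sparing prevalence. **No multiple-testing adjustment is
  applied anywhere**; p-values are reported raw.

## CLI

```sh
# synthetic phantom study (NIfTI volume + masks, JSON meta + labels)
spectquant phantom --out study/ --seed 1 --psf-fwhm-mm 12 --count-scale 50

# per-region metrics table (optionally reorienting volume and masks jointly)
spectquant quantify --volume study/volume.nii.gz --masks study/masks.nii.gz \
    --meta study/meta.json --labels study/labels.json \
    --fraction 0.42 --sternum-margin-mm 10 --rotate 25,10,0 --out metrics.csv

# synthetic cohort and its correlation report
spectquant cohort --n 48 --seed 1 --out cohort.csv
spectquant report --cohort cohort.csv --out report.csv
```

`metrics.csv` has one row per region (`LV_LATERAL`, `IVS`, `APEX`,
`RV_FREE_WALL`, `LV`, `VENTRICLES`) with columns `dpd_mean`, `dpd_max`,
`v42_ml`, `dpd_load`, `n_voxels_anatomical`, `n_voxels_thresholded`.

Cohort CSV columns: `{dpd_load,dpd_mean,dpd_max}_{region}` for the six
regions, `strain_{region}` for the five strain regions, `troponin_t`,
`nt_probnp`, `perugini_grade`, and `apical_avg_strain` /
`basal_avg_strain` / `mid_avg_strain` feeding the echo sparing ratio.
Missing entries are empty cells (complete-case handling downstream).

## Metadata format

`meta.json` is flat JSON: `injected_activity_MBq`, `injection_time` and
`acquisition_time` (ISO-8601), `body_weight_kg`, and optional `half_life_h`
(default 6.0067, Tc-99m).
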