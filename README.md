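# petbtv

Tools for asking a focused question in radiotherapy planning for locally
advanced pancreatic cancer (LAPC): **does the high-uptake subvolume on a
baseline FDG-PET predict *where* metabolic activity survives
chemoradiotherapy (CRT)?** If it does, the baseline subvolume is a candidate
biological target volume (BTV) for a selective radiation dose boost.

The package implements the full analysis chain on paired pre/post-CRT
PET/CT:

- **SUV quantification** — body-weight standardized uptake value,
  `SUV = activity [Bq/ml] × weight [g] / dose [Bq]`, with SUVmax taken as the
  hottest voxel inside an axis-aligned elliptical ROI; weight-based dosing
  (4 MBq/kg, capped at 600 MBq) and an eligibility screen (metabolic
  complete response, non-avid tumour, missing post scan, inseparable
  uptake, elevated blood glucose).
- **Threshold segmentation** — subvolumes at a percentage of SUVmax
  (40/50 % at baseline; 60/70/80/90 % post-CRT, where shrunken uptake and
  the scanner recovery coefficient demand higher relative cuts) or at an
  absolute SUV (e.g. 2.5); inclusive threshold, single 26-connected
  component containing the SUVmax voxel.
- **Contour propagation** — a deterministic translation-only rigid
  pre-alignment, plus propagation of post-CRT masks to the planning grid
  through a dense deformation field (pull-back convention, trilinear
  resampling, 0.5 re-binarization) with Jacobian-based field validation.
  The non-rigid optimizer itself is out of scope; fields are inputs.
- **Overlap statistics** — the overlap fraction
  `OF(A|B) = 100·|A∩B|/|B|` with the post-CRT (or GTV) volume as reference,
  cohort mean/range/median summaries, and the two-tailed paired t-test on
  SUVmax.
- **Synthetic phantoms** — paired pre/post-CRT volumes with exact ground
  truth (GTV mask, residual mask, deformation field): truncated-Gaussian
  uptake, a controlled containment fraction of the residual hot region
  inside the baseline 40 % region, shrinkage + caudal shift response,
  Gaussian PSF blur and seeded voxel noise.
- **Cohort fixtures** — per-patient transcriptions of the published
  17-patient cohort (SUVmax, volumes, overlap fractions) and a synthetic
  eligibility-flag table reproducing the published 17 → 9 accounting.

## Worked example

```python
from petbtv import PhantomSpec, run_phantom_patient

# a Patient-1-like response: tumour shrinks to 80 % and moves 15 mm caudally,
# residual uptake 90 % contained in the baseline 40 % subvolume
spec = PhantomSpec(shrinkage=0.8, caudal_shift=15.0, containment_fraction=0.9,
                   noise_sd=0.0, psf_fwhm=0.0)
pair, res = run_phantom_patient(spec)
print(res.suv_max_pre, res.suv_max_post)
print({k: round(v, 1) for k, v in res.overlaps_pct.items()})
```

prints

```
8.0 3.6
{'Pre40|Post90': 100.0, 'Pre40|Post80': 100.0, 'Pre40|Post70': 100.0,
 'Pre40|Post60': 100.0, 'Pre50|Post90': 100.0, 'Pre50|Post80': 100.0,
 'Pre50|Post70': 100.0, 'Pre50|Post60': 88.9}
```

i.e. once the post-CRT subvolumes are propagated back through the true
deformation field, essentially all residual activity lies inside the
baseline Pre40 % subvolume — the geometric signature of a predictive BTV.
Running the same phantom with the field ignored (`use_true_field=False`)
collapses the overlaps to near zero, which is why registration is part of
the chain. And from the shipped cohort tables:

```python
from petbtv import reproduce_tables
report = reproduce_tables()
print(report[["quantity", "computed", "published"]].head(4).to_string(index=False))
```

```
         quantity  computed  published
analysis_set_size       9.0        9.0
      mean_GTV_cc      41.3       41.3
   mean_Pre40%_cc      19.9       19.9
   mean_Pre50%_cc      12.1       12.1
```

A `petbtv` command exposes the same steps from a shell
(`petbtv phantom generate`, `petbtv segment`, `petbtv warp`,
`petbtv overlap`, `petbtv cohort reproduce-tables`, `petbtv cohort filter`).

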