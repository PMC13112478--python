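# cardiac4d

Segmentation, label propagation and functional validation for **isotropic 4D
cardiac cine MRI** (3D space + cardiac phase).

Free-breathing, ECG-free whole-heart acquisitions reconstruct into isotropic
4D image series — typically 1.4 mm voxels over 20+ cardiac frames, i.e. tens
of thousands of short-axis images per subject. Manual contouring at that scale
is impossible, which blocks the extraction of routine clinical measures
(ventricular volumes, ejection fraction) from such data. `cardiac4d`
implements the full desk-scale workflow around this problem, for researchers
developing or validating 4D segmentation pipelines:

* **phantom** — seeded synthetic 4D beating hearts (truncated-ellipsoid LV
  blood pool + volume-conserved myocardial shell + crescent RV) with
  closed-form ground-truth volumes, standing in for non-shareable patient
  data;
* **propagate** — the semi-automatic ground-truth engine: sparse expert key
  slices are extended through the volume (3D) or from end-diastole/end-systole
  to every cardiac phase (4D) by chained diffeomorphic demons registrations on
  a stationary velocity field (positive Jacobian guaranteed by
  scaling-and-squaring);
* **reorient** — rigid reformatting between the acquisition frame and
  double-oblique short-axis axes with label-safe resampling;
* **segmenter** — a compact trainable segmentation stage under the standard
  contract: stratified 5-fold cross-validation, soft-Dice loss over the
  foreground classes (LV blood pool, LV myocardium, RV blood pool), per-phase
  3D inference, largest-connected-component post-processing;
* **cardiometrics** — three validation tiers: geometric (Dice, Hausdorff,
  average symmetric surface distance, relative volume difference, pooled over
  ED and ES), clinical (EDV/ESV, EF = (EDV−ESV)/EDV·100, SV = EDV−ESV for both
  ventricles), and physiological consistency (systole–diastole myocardial
  volume mismatch ε_LVM = |EDV_LVM − ESV_LVM| / mean, LV–RV stroke-volume
  agreement within 10 mL in healthy subjects);
* **stats_report** — Bland–Altman bias and limits of agreement, ICC(2,1),
  standard error of measurement, paired tests with a Shapiro–Wilk gate,
  repeated-measures ANOVA with Tukey HSD, and batch report tables.

## Worked example

```python
from cardiac4d import phantom, propagate, cardiometrics as cm

# a default phantom: 96^3 voxels at 1.4 mm, 20 phases, EDV 150 mL, EF 60%
params = phantom.PhantomParams()
cine, truth = phantom.generate_phantom(params)
print(truth.ed_phase, truth.es_phase)           # 0 8

# sparse expert annotation at every 5th short-axis slice, then 3D propagation
keys = phantom.simulate_key_slice_annotations(truth.labels, truth.ed_phase, step=5)
labels = propagate.propagate_labels_3d(cine.phase(truth.ed_phase), keys,
                                       spacing_mm=cine.spacing_mm)
for code, name in [(1, "LVB"), (2, "LVM"), (3, "RVB")]:
    print(name, round(cm.dice(labels == code,
                              truth.labels.voxels[..., truth.ed_phase] == code), 3))
# LVB 0.995
# LVM 0.988
# RVB 0.993

# clinical metrics from the truth labels
ed, es = cm.detect_ed_es(truth.labels)
met = cm.clinical_metrics(truth.labels, ed, es)
print(round(met.lv.edv_ml, 1), round(met.lv.ef_pct, 1))
# 150.9 60.6
```

The Dice values show that registration-based propagation reconstructs ~99% of
each structure from one-fifth of the slices; the clinical readouts recover the
phantom's designed EDV (150 mL) and EF (60%) to within voxelisation error.

A command-line interface mirrors the library (`cardiac4d --help`):
`phantom-generate`, `reorient`, `propagate-3d`, `propagate-4d`, `train`,
`infer`, `postprocess`, `evaluate`. Every command writes a JSON run log with
the config hash and seed.

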