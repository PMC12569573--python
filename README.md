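# lvnckit

A toolkit for quantifying left-ventricular trabeculation in short-axis
cardiac MRI, aimed at left-ventricular non-compaction (LVNC) analysis
pipelines.  It covers the full chain from raw slice to diagnosis flag:

* **Synthetic LV phantoms** — procedurally generated short-axis slices with
  four-class ground truth (background, compact external layer *EL*, inner
  cavity *IC*, trabeculae *T*), patient stacks and four-group cohorts
  (P/H/X/T), including the degenerate "no ring" and "poor quality" slice
  categories.  Every other stage is testable without any clinical data.
* **Mask geometry** — largest-contour extraction, tight LV bounding boxes
  and normalised detection labels, plus cardiac-phase selection (largest
  cavity box = end-diastole, smallest = end-systole).
* **Detector-guided ROI preprocessing** — confidence-adaptive square crops
  (`l_resize = max(w, h) · (1 + (1 − prob))`), resizing to a standard side
  (800 px by default) and z-score normalisation.
* **Segmentation network** — a hybrid CNN–transformer U-Net: convolutional
  encoder, ViT bottleneck with self-attention, skip-fused decoder and a
  four-class softmax head.  Trained with the sum of the Lovász-Softmax loss
  and a class-weighted binary cross-entropy under RAdam (lr 0.005), with
  right-angle rotation augmentation (p = 0.25) and patient-level stratified
  5-fold cross-validation.  The engine is pure numpy with hand-written
  backpropagation — no deep-learning framework required.
* **Slice quality control** — a two-stage linear rule cascade over detector
  triplets `(Conf-Valid-IC, Conf-Open-IC, Area-bbox-Valid-IC)`: stage 1
  discards when `conf_open − 5.526·conf_valid > −4.3`; stage 2 keeps slices
  with `conf_valid ≥ 0.88`, rejects below `0.83`, and inside the band
  applies a negative-slope confidence/area trade-off line.  Patient TV% is
  readjusted over the surviving slices.
* **Quantification & evaluation** — per-class areas, the trabecular volume
  percentage

  ```
  TV% = 100 · T / (T + EL)
  ```

  summed over a patient's slices, the LVNC decision `TV% > 27.4`, and
  per-class / per-group Dice reporting.

## Worked example

```python
from lvnckit.phantoms import PhantomSpec, generate_patient, simulate_qc_triplet
from lvnckit.quantify import patient_tv, classify_lvnc
from lvnckit.cleaning import QCTriplet, clean_slice

study = generate_patient(
    "H", spec_template=PhantomSpec(trabecular_fraction=0.35), seed=7
)
masks = [m for _, m in study.slices]
tv = patient_tv(masks)
print(f"patient {study.patient_id}: TV% = {tv:.2f}, LVNC = {classify_lvnc(tv)}")

t = simulate_qc_triplet(*study.slices[3], study.slice_specs[3], seed=3)
print(f"slice 3 triplet: conf_valid={t.conf_valid:.3f} "
      f"conf_open={t.conf_open:.3f} area={t.area:.3f}")
print("decision:", clean_slice(t).value)
print("decision for (0.50, 0.10, 0.03):", clean_slice(QCTriplet(0.50, 0.10, 0.03)).value)
```

prints

```
patient H0000: TV% = 35.00, LVNC = True
slice 3 triplet: conf_valid=0.953 conf_open=0.036 area=0.253
decision: keep
decision for (0.50, 0.10, 0.03): discard_stage1
```

The phantom patient was generated at a target trabecular fraction of 0.35,
and summed-area quantification recovers TV% = 35.00, above the 27.4 %
threshold, so the LVNC flag raises.  A clean, well-detected mid-stack slice
(high cavity confidence, low open-ring confidence, large cavity area) is
kept by the quality cascade, while a weakly detected cavity
(`conf_valid = 0.50`) falls on the discard side of the stage-1 boundary.

## Command line

`lvnckit` exposes the stages as subcommands, each accepting `--config`
(YAML) and `--seed`:

```bash
lvnckit synth --n 8 --out cohort --seed 1        # phantom cohort + triplets
lvnckit labels --manifest cohort/manifest.csv --out labels
lvnckit roi --manifest cohort/manifest.csv --out rois --out-size 128
lvnckit train --manifest cohort/manifest.csv --out model.npz --epochs 5
lvnckit segment --model model.npz --manifest cohort/manifest.csv --out preds
lvnckit clean --triplets cohort/triplets.csv --out cleaned
lvnckit quantify --manifest cohort/manifest.csv --out tv.csv
lvnckit evaluate --pred-dir preds --manifest cohort/manifest.csv --out dice.json
```

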