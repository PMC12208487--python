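# usaug

Ultrasound-specific, annotation-aware data augmentation and dataset
engineering for YOLO-format object-detection datasets, plus
annotation-quality auditing against a gold standard. Built for grayscale
thyroid-nodule ultrasound images but agnostic to the actual detector: it
prepares and audits the data, it never trains a model.

## What it does

- **`usaug.yolo_dataset`** — read/write 8-bit grayscale images, YOLO label
  text files (`class cx cy w h [conf]`, normalized center format), YAML
  dataset manifests, and per-class nodule count tables.
- **`usaug.augment_ops`** — pure, seeded augmentation operators:
  - *defocus*: 5×5 Gaussian-kernel convolution (stride 1, replicate
    padding), σ controls blur strength;
  - *shadow_box*: fast acoustic-shadow approximation — a rectangle darkened
    by an adjustable alpha;
  - *sidelobe*: a faint rotated copy of the image blended back onto itself;
  - *brightness / contrast*: linear intensity maps with clipping;
  - *rotation*: small-angle rotation with box corners re-hulled, clipped,
    and dropped below a minimum surviving-area fraction.
  Every applied op is recorded as a serializable `AugSpec`, so any output
  image is exactly reproducible.
- **`usaug.shadow_field`** — physics-inspired graded acoustic-shadow
  simulator: a shadow front marched line-by-line behind an occluder, with
  lateral Gaussian diffusion and per-line decay; renderable as contours.
- **`usaug.balance_plan`** — class-imbalance-driven planner: derives
  per-class targets from the largest class, selects images containing
  under-represented classes (with replacement), and assigns each selected
  copy exactly two distinct randomly chosen ops. Plans are deterministic
  given a seed and their projected class counts match execution exactly.
- **`usaug.batch_split`** — reproducible 25-portion partition with a
  5-batch cumulative schedule (batch N uses the first 5·N portions; 4:1
  train/validation portions per block).
- **`usaug.annot_eval`** — confidence filtering, class-agnostic NMS, greedy
  IoU matching to gold labels, confusion matrices with an explicit
  background row/column, per-class/overall accuracy, and mAP50 / mAP50-95.
- **`usaug.phantom_synth`** — synthetic speckle phantom generator
  (fan-sector rasters, elliptical nodules with known boxes and a
  configurable class-imbalance profile) plus a label corrupter that
  simulates an imperfect annotator via a row-stochastic error matrix.
- **`usaug.cli_config`** — YAML config with strict schema checking and an
  exported trainer-settings template for an external detector.

## CLI

A single `usaug` entry point with subcommands (all sampling commands require
an explicit `--seed`):

```bash
usaug synth --out data/ --n-images 100 --image-size 128 --seed 1
usaug stats data/manifest.yaml --csv counts.csv
usaug balance data/manifest.yaml --target-ratio 2 --seed 1 --out balanced/
usaug split data/manifest.yaml --portions 25 --batches 5 --seed 1 --out splits/
usaug eval --pred pred_labels/ --gold gold_labels/ \
    --manifest data/manifest.yaml --match-iou 0.5 --conf 0.1 --nms-iou 0.7 \
    --out report/
usaug shadowsim --occluder mask.png --direction down-right \
    --out field.npy --plot field.png
usaug export-config --out trainer.yaml
```

`balance` writes augmented images, labels, a JSON sidecar recording every
applied `AugSpec`, and before/after class-count tables (CSV + bar chart).
`eval` writes confusion-count and proportion CSVs plus a metrics JSON
(accuracy and mAP).

## Notes

- Operators never contain randomness; parameters are sampled once by the
  planner and frozen into `AugSpec`s, so augmentation runs are byte-for-byte
  repeatable.
- Multi-nodule images carry one label file with multiple lines (standard
  YOLO layout).
- The exported trainer template records the detector settings verbatim; this
  package does not execute them.
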