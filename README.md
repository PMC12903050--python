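# chipcell

Cell detection and killing-assay quantification for bright-field images of
microfluidic trap arrays.

Suspension cells trapped in PDMS chambers are hard to detect with classical
image processing: the refractive-index mismatch makes channel walls highly
visible, and trapped cells form dense touching clusters. `chipcell`
implements a complete pipeline around a compact two-stage region-proposal
detector (fixed generic feature pyramid, learned anchor-scoring proposal
stage, learned classification + box-refinement head) that fine-tunes on a
handful of bounding-box annotations, plus:

- **synthgen** — synthetic chamber scenes, whole-array mosaics and paired
  bright-field/fluorescence time-lapses with exact ground truth (4 chamber
  layouts, 1–15 textured cells, controllable defocus blur, noise calibrated
  to a target intensity RSD);
- **annot_io** — Pascal VOC XML and flat inference-CSV I/O (COCO JSON read);
- **detector** — train / infer / confidence filtering, deterministic in the
  seed; models persist as a single `.npz` archive;
- **baseline_hough** — circular-Hough baseline with a 5–100 px radius band
  filter, emitting the same detection format;
- **evalkit** — IoU, greedy TP/FP/FN matching, precision/recall, all-point
  average precision, training-set-size and annotator-variability studies;
- **arraysplit** — whole-array → per-chamber cropping with oversize and
  edge filtering and exact coordinate mapping back to array space;
- **assay** — time-lapse quantification: constant-count detection (top-N
  selection matching the t0 count), per-cell ROI fluorescence, bimodal
  live/dead thresholding, trajectories and survival curves.

## CLI

All stages are exposed as `chipcell` subcommands; defaults follow the
working thresholds (confidence 0.9, IoU 0.5). Every run writes a
`provenance.json` (config hash, seeds, versions).

```bash
chipcell synth --out data/train --n-images 4  --seed 1      # synthetic dataset
chipcell synth --out data/test  --n-images 60 --seed 2
chipcell train --data data/train --out model.npz --epochs 200 --stop-loss 0.15 --seed 0
chipcell infer --model model.npz --images data/test --out preds.csv --conf 0.9
chipcell eval  --pred preds.csv --gt data/test --iou 0.5 --conf 0.9
chipcell hough --images data/test --out hough.csv --radius-min 5 --radius-max 100
chipcell split --model chamber.npz --image array.tif --out crops/
chipcell assay --bf frames/bf --fl frames/fl --model model.npz --out assay/
chipcell study-size --sizes 1,40 --replicates 5 --out study.csv
chipcell study-annotators --n-annotators 3 --out annot.csv
```

A YAML config can supply shared defaults (`chipcell --config run.yaml ...`);
explicit flags win.

## Notes

- All randomness flows through explicit integer seeds; training and
  inference are bit-deterministic single-threaded.
- Internal box convention is 0-based half-open; only the VOC layer converts
  to VOC's 1-based inclusive pixels.
- `average_precision` (area under the PR curve over all confidence cutoffs)
  and `precision_at_threshold` (fixed cutoff, default 0.9) are reported side
  by side; they are different quantities.
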