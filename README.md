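# glowlabel

Fluorescence-derived landmark label synthesis and detector evaluation,
exercised entirely on synthetic imagery.

A hidden fluorescent dye that is visible only under UV excitation can label a
moving subject automatically: UV and visible illumination are strobed
alternately, the dye blob is segmented and its centroid becomes the label for
the next visible frame.  A speckled dye pattern generalizes this to many
landmarks at once — local neighborhoods act as visual barcodes (SIFT
keypoints) matched between frames, cleaned by a spatial-coherency filter, and
turned into labels by median pooling over annotated template regions or by
local-homography propagation of spacing-constrained landmark features.  The
package implements both labeling pipelines plus training-target generation
and detector evaluation with test-time scale optimization, with seeded
synthetic fixtures standing in for real recordings.

## Modules

| Module                  | Role |
| ----------------------- | ---- |
| `glowlabel.acquisition` | Strobe-cycle trigger schedules (biphasic/triphasic) and UV→visible frame pairing |
| `glowlabel.serial`      | Dye-mask extraction (threshold → morphology), centroid labels, absent handling, temporal interpolation |
| `glowlabel.barcode`     | SIFT barcode detection, descriptor matching, δ/ε spatial-coherency filtering, per-region match counts |
| `glowlabel.atlas`       | K-means feature clustering and greedy cluster-weighted template ranking with coverage curves |
| `glowlabel.propagation` | Median pooling, auto landmark selection, local-homography propagation, segmentation masks, background compositing, stride-reduced training targets with interleaved loss masks, augmentation, COCO/CSV export |
| `glowlabel.evaluation`  | Pixel error, on-target precision/recall/AUC, two-level test-time scale search, rolling confidence traces |
| `glowlabel.fixtures`    | Seeded synthetic generators: moving-dye sequences, speckle scenes under known warps, mock detectors |
| `glowlabel.pipeline`    | YAML-configured multi-stage runner with hashed artifact manifests |

## CLI

```sh
glowlabel simulate serial  --seed 0 --out fixture/        # synthetic dye sequence
glowlabel simulate speckle --seed 0 --out speckle/        # speckle scene + warps
glowlabel pair --manifest fixture/frames.csv --max-gap-ms 7.5 --out pairs.csv
glowlabel serial-label --pairs pairs.csv --out track.csv
glowlabel match --template speckle/template.png --target speckle/frame_0000.png \
    --delta 50 --epsilon 50 --out matches.csv
glowlabel propagate --template t.png --target f.png --mode auto --k 10 \
    --radius 30 --out labels.csv
glowlabel eval --pred preds.csv --truth track.csv --width 848
glowlabel scaleopt --detector-cmd 'python det.py' --frames-dir frames/ --level clip
glowlabel run --config pipeline.yaml                      # full staged pipeline
```

A pipeline config names stages in order with per-stage parameter blocks;
unknown keys are rejected, every output file is hashed into
`manifest.json`, and per-stage seeds derive from the master seed so reruns
are bit-identical:

```yaml
seed: 0
out_dir: out
stages:
  - stage: simulate_serial
    params: {n_frames: 50, occlusion_frames: [10, 11]}
  - stage: pair
    params: {max_gap_ms: 7.5}
  - stage: serial_label
  - stage: export_labels
    params: {landmark_name: hand}
```

## Conventions

Coordinates are continuous, 0-based, pixel-center, origin top-left,
x rightward, y downward.  Absent labels are first-class (`present=False`,
NaN coordinates) and encode as COCO visibility 0.  All randomness flows
through explicit integer seeds.
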