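# spheromon

Automated, high-throughput monitoring of cell aggregation into
microspheroids in agarose microwell arrays, from bright-field time-lapse
images.

Given a time-lapse of a microwell array (cylindrical wells, nominally 200 µm
diameter / 100 µm spacing, ≈75 px inner radius at the supported 4× setup),
the pipeline:

1. **detects microwells** per frame — Roberts gradient, fixed threshold
   (0.015), two-stage circular Hough transform (radius range 80–86 px,
   sensitivity 0.975, edge threshold 0.030), then false-positive removal by
   relative circle strength and the fixed inter-well spacing, keeping only
   wells completely inside the field of view;
2. **segments the spheroid** in each well — adaptive Otsu threshold on the
   in-well intensities OR-combined with a fixed gradient threshold (0.020),
   AND-combined with the circular well mask, followed by a four-step
   morphological cleanup (keep-largest with ≤25 px small-object retention;
   bridge + diagonal fill; ≤150 px hole fill with an r=2 disk opening;
   second bridge/diagonal fill and final hole fill);
3. **extracts morphology** — area, perimeter (weighted boundary chain),
   minor/major axis (moments ellipse), roundness, circularity, equivalent
   diameter, eccentricity, solidity, in pixels and physical units;
4. **tracks wells over time** (greedy mutual-nearest-neighbour linking;
   re-entering wells start new tracks) and aggregates population-level
   mean ± SD time series;
5. **validates quantitatively** — per-feature relative error, pixel-level
   sensitivity (TPR) and precision (PPV), per-set summary tables, and
   semi-transparent red mask overlays.

Because no raw microscopy data ships with this package, a **phantom module**
generates synthetic microwell time-lapses with exact ground truth (dark
irregular rims, fragments aggregating into compact blobs by first-order
kinetics, shading, blur, noise, stage drift), including a four-set
validation benchmark (~60 wells per set) that mirrors the original
small/large × initial/final validation design.

## CLI

```sh
# synthetic data with ground truth
spheromon phantom --preset validation --seed 7 --out data/bench
spheromon phantom --preset timelapse  --seed 0 --out data/tl   # 193 frames, 5 min

# full pipeline over a frame directory (TIFF/PNG, numeric suffix ordering)
spheromon run --input data/tl --pattern 'frame_*.tif' --out out/ --save-overlays

# compare predicted vs reference masks (matching PNG filenames)
spheromon validate --truth data/bench/set1/truth --pred out/masks --out out/val

# annotated animation of the overlays (default 5 fps)
spheromon video --run out/ --out out/movie.gif
```

`spheromon run` writes `detections.csv`, `features.csv` (long format),
`tracks.csv`, `population_summary.csv` and a `manifest.json` with the config
digest and per-stage counts. All parameters live in a YAML config
(`--config cfg.yaml`) with blocks `detection:`, `segmentation:`,
`tracking:`; defaults match the reference setup (pixel size 1.333 µm/px,
frame interval 5 min).

Note: focus mapping is an acquisition-time concern and is out of scope here;
frames are assumed focused.

## Layout

```
src/spheromon/
  phantom.py      synthetic frame/truth generator + benchmark presets
  well_detect.py  Roberts gradient, thresholding, two-stage Hough, filtering
  segment.py      well masks, Otsu, morphology primitives, cleanup chain
  features.py     moments, perimeter chain, shape descriptors
  track.py        frame linking, population statistics
  metrics.py      relative error, TPR/PPV, set summaries, overlays
  pipeline.py     orchestration, artifacts, video export
  benchmark.py    end-to-end benchmark scoring
  config.py       parameter blocks + YAML round-trip
  cli.py          click entry points
```
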