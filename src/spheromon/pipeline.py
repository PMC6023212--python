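"""End-to-end orchestration: read frames, detect wells, segment spheroids,
extract features, track over time, and write reproducible run artifacts."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .features import FeatureRecord, extract_features
from .metrics import overlay
from .segment import SpheroidMask, segment_spheroid
from .track import Track, Tracker, population_average, tracks_to_table
from .well_detect import Frame, WellDetection, detect_wells, roberts_gradient

log = logging.getLogger("spheromon")

_POPULATION_FEATURES = ("area_px", "circularity", "roundness", "perimeter_px")


@dataclass
class FrameResult:
    frame_index: int
    time_min: float
    detections: list[WellDetection]
    masks: list[SpheroidMask]
    features: list[FeatureRecord]


@dataclass
class RunResult:
    config: RunConfig
    frames: list[FrameResult] = field(default_factory=list)
    tracks: list[Track] = field(default_factory=list)
    skipped_frames: list[str] = field(default_factory=list)

    @property
    def detections_table(self) -> pd.DataFrame:
        rows = []
        for fr in self.frames:
            for wid, d in enumerate(fr.detections):
                rows.append(
                    {
                        "frame": fr.frame_index,
                        "time_min": fr.time_min,
                        "well_id": wid,
                        "cx": d.cx,
                        "cy": d.cy,
                        "r": d.radius,
                        "strength": d.strength,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def features_table(self) -> pd.DataFrame:
        rows = []
        for fr in self.frames:
            for wid, (d, feat) in enumerate(zip(fr.detections, fr.features)):
                row = {
                    "frame": fr.frame_index,
                    "time_min": fr.time_min,
                    "well_id": wid,
                    "well_cx": d.cx,
                    "well_cy": d.cy,
                }
                row.update(feat.as_dict())
                rows.append(row)
        return pd.DataFrame(rows)


def process_frame(frame: Frame, config: RunConfig) -> FrameResult:
    """Detection + segmentation + feature extraction for one frame."""
    grad = roberts_gradient(frame)
    detections = detect_wells(frame, config.detection)
    if not detections:
        log.warning("frame %d: zero wells detected", frame.frame_index)
    masks, feats = [], []
    for wid, det in enumerate(detections):
        mask = segment_spheroid(frame, grad, det, config.segmentation, well_id=wid)
        masks.append(mask)
        feats.append(extract_features(mask, config.pixel_size_um))
        if mask.empty_flag:
            log.debug("frame %d well %d: empty mask", frame.frame_index, wid)
    return FrameResult(frame.frame_index, frame.time_min, detections, masks, feats)


def run_frames(frames, config: RunConfig) -> RunResult:
    """Run the full pipeline over an in-memory frame sequence."""
    config.validate()
    result = RunResult(config=config)
    tracker = Tracker(max_shift=config.tracking.max_shift_px)
    for frame in frames:
        fr = process_frame(frame, config)
        result.frames.append(fr)
        tracker.update(fr.frame_index, fr.time_min, fr.detections, fr.features)
    result.tracks = tracker.tracks
    return result


def _frame_sort_key(path: Path):
    """Frames are ordered by the numeric suffix of the stem, then by name."""
    digits = ""
    for ch in reversed(path.stem):
        if ch.isdigit():
            digits = ch + digits
        elif digits:
            break
    return (int(digits) if digits else -1, path.name)


def load_frames(config: RunConfig):
    """Yield frames from the input directory, ordered by numeric suffix.
    Unreadable files are logged and skipped (tracking records a gap)."""
    import imageio.v3 as iio

    paths = sorted(Path(config.input_dir).glob(config.pattern), key=_frame_sort_key)
    if not paths:
        raise FileNotFoundError(
            f"no frames matching {config.pattern!r} in {config.input_dir}"
        )
    for idx, path in enumerate(paths):
        try:
            arr = iio.imread(path)
        except Exception as exc:  # corrupt frame: log, skip, keep the gap
            log.error("skipping unreadable frame %s: %s", path.name, exc)
            yield None, path
            continue
        yield Frame.from_array(
            arr, frame_index=idx, time_min=idx * config.frame_interval_min
        ), path


def run_timelapse(config: RunConfig) -> RunResult:
    """Process a time-lapse directory and write all run artifacts."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    result = RunResult(config=config)
    tracker = Tracker(max_shift=config.tracking.max_shift_px)
    frame_files = []
    for frame, path in load_frames(config):
        frame_files.append(path.name)
        if frame is None:
            result.skipped_frames.append(path.name)
            continue
        fr = process_frame(frame, config)
        result.frames.append(fr)
        tracker.update(fr.frame_index, fr.time_min, fr.detections, fr.features)
        if config.save_masks:
            _save_masks(out / "masks", fr)
        if config.save_overlays:
            _save_overlay(out / "overlays", frame, fr)
    result.tracks = tracker.tracks

    write_artifacts(result, out, frame_files)
    return result


def write_artifacts(
    result: RunResult, out: Path, frame_files: list[str] | None = None
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.detections_table.to_csv(out / "detections.csv", index=False)
    result.features_table.to_csv(out / "features.csv", index=False)
    tracks_to_table(result.tracks).to_csv(out / "tracks.csv", index=False)
    if result.tracks:
        pop = pd.concat(
            [population_average(result.tracks, f) for f in _POPULATION_FEATURES],
            ignore_index=True,
        )
        pop.to_csv(out / "population_summary.csv", index=False)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": result.config.to_dict(),
        "config_digest": result.config.digest(),
        "frame_files": frame_files or [],
        "skipped_frames": result.skipped_frames,
        "per_frame_counts": [
            {
                "frame": fr.frame_index,
                "detected": len(fr.detections),
                "empty_masks": sum(m.empty_flag for m in fr.masks),
            }
            for fr in result.frames
        ],
        "n_tracks": len(result.tracks),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _save_masks(mask_dir: Path, fr: FrameResult) -> None:
    from PIL import Image

    mask_dir.mkdir(parents=True, exist_ok=True)
    for wid, mask in enumerate(fr.masks):
        img = Image.fromarray((mask.pixels * 255).astype(np.uint8))
        img.save(mask_dir / f"well{wid:03d}_f{fr.frame_index:04d}.png")


def _save_overlay(ov_dir: Path, frame: Frame, fr: FrameResult) -> None:
    from PIL import Image

    ov_dir.mkdir(parents=True, exist_ok=True)
    rgb = overlay(frame, fr.masks)
    img = Image.fromarray(np.round(rgb * 255).astype(np.uint8))
    img.save(ov_dir / f"overlay_f{fr.frame_index:04d}.png")


def export_video(
    run_dir: str | Path,
    out_path: str | Path,
    fps: float = 5.0,
    annotate: bool = True,
) -> Path:
    """Assemble the run's overlay frames into an animated GIF at ``fps``.

    Frames are annotated with per-well area and circularity read from the
    feature table.  (GIF rather than AVI/MP4: no external video encoder is
    assumed to be installed.)
    """
    from PIL import Image, ImageDraw

    run_dir = Path(run_dir)
    ov_dir = run_dir / "overlays"
    paths = sorted(ov_dir.glob("overlay_f*.png"))
    if not paths:
        raise FileNotFoundError(f"no overlays under {ov_dir}; rerun with save_overlays")
    feats = pd.read_csv(run_dir / "features.csv") if annotate else None
    images = []
    for path in paths:
        img = Image.open(path).convert("RGB")
        fidx = int(path.stem.split("overlay_f")[1])
        if feats is not None and not feats.empty:
            draw = ImageDraw.Draw(img)
            sub = feats[feats["frame"] == fidx]
            for _, row in sub.iterrows():
                if row.get("empty_flag", False) or not np.isfinite(row["area_px"]):
                    continue
                text = f"A={row['area_px']:.0f}\nC={row['circularity']:.2f}"
                draw.text((row["well_cx"] - 30, row["well_cy"] - 10), text, fill=(255, 255, 0))
        images.append(img)
    out_path = Path(out_path)
    duration_ms = int(round(1000.0 / fps))
    images[0].save(
        out_path,
        save_all=True,
        append_images=images[1:],
        duration=duration_ms,
        loop=0,
    )
    return out_path
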