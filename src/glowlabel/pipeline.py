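"""Configuration-driven pipeline runner with provenance manifest.

A pipeline is a YAML config naming stages in dependency order; each stage
reads and writes files under the output directory, and every output is
recorded in a manifest with its content hash, so identical config + seed
reproduce identical manifests.  Per-stage seeds are derived from the master
seed by stable hashing, making stages independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Callable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import acquisition, atlas, barcode, propagation, serial
from .errors import ConfigError, StageError
from .fixtures import (
    SerialFixtureSpec,
    SpeckleFixtureSpec,
    gen_serial_sequence,
    gen_speckle_scene,
)

logger = logging.getLogger("glowlabel.pipeline")

_TOP_KEYS = {"seed", "out_dir", "log_level", "stages"}
_STAGE_KEYS = {"stage", "params"}

# allowed parameter keys per stage
_STAGE_PARAMS: dict[str, set[str]] = {
    "simulate_serial": {
        "n_frames", "width", "height", "blob_radius_px", "blob_intensity",
        "background_intensity", "texture_amplitude", "path", "path_start",
        "path_end", "occlusion_frames",
    },
    "pair": {"max_gap_ms"},
    "serial_label": {
        "threshold", "threshold_floor", "open_radius_px", "close_radius_px",
        "min_area_px", "max_components",
    },
    "interpolate": {"method", "max_absent_span"},
    "export_labels": {"landmark_name"},
    "parallel_demo": {
        "width", "height", "n_spots", "warp", "matrix", "translation",
        "contrast_threshold", "min_spacing_px", "neighborhood_radius_px",
        "min_neighbors", "delta_px", "epsilon_px",
    },
}


def stage_seed(master_seed: int, stage_name: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage_name}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: Mapping[str, Any]) -> None:
    """Reject unknown keys anywhere in the config, naming the offender."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key {sorted(unknown)[0]!r}")
    if "stages" not in config or "out_dir" not in config:
        raise ConfigError("config requires 'stages' and 'out_dir'")
    for entry in config["stages"]:
        unknown = set(entry) - _STAGE_KEYS
        if unknown:
            raise ConfigError(f"unknown stage key {sorted(unknown)[0]!r}")
        name = entry.get("stage")
        if name not in _STAGE_PARAMS:
            raise ConfigError(f"unknown stage {name!r}")
        params = entry.get("params") or {}
        bad = set(params) - _STAGE_PARAMS[name]
        if bad:
            raise ConfigError(
                f"unknown key {sorted(bad)[0]!r} in stage {name!r}"
            )


def _save_image(path: Path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


def _load_image(path: str) -> np.ndarray:
    return np.asarray(iio.imread(path), dtype=float) / 255.0


# ---------------------------------------------------------------------------
# stage implementations; each returns a list of written files


def _stage_simulate_serial(params: dict, out: Path, seed: int) -> list[Path]:
    kwargs = dict(params)
    if "occlusion_frames" in kwargs:
        kwargs["occlusion_frames"] = frozenset(kwargs["occlusion_frames"])
    for key in ("path_start", "path_end"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    spec = SerialFixtureSpec(seed=seed, **kwargs)
    fix = gen_serial_sequence(spec)
    frame_dir = out / "frames"
    frame_dir.mkdir(parents=True, exist_ok=True)
    written = []
    records = []
    for rec, img in zip(
        fix.frames,
        (im for pair in zip(fix.uv_frames, fix.visible_frames) for im in pair),
    ):
        path = frame_dir / f"{rec.illumination}_{rec.index:05d}.png"
        _save_image(path, img)
        # manifest paths are relative to the output directory so that
        # identical configs hash identically regardless of where they run
        records.append(
            acquisition.FrameRecord(
                rec.index,
                rec.timestamp_ms,
                rec.illumination,
                rec.camera_id,
                str(path.relative_to(out)),
            )
        )
        written.append(path)
    manifest_path = out / "frames.csv"
    acquisition.write_manifest(records, manifest_path)
    truth_path = out / "truth.csv"
    serial.write_track(fix.truth, truth_path)
    meta = out / "fixture.yaml"
    with open(meta, "w") as fh:
        yaml.safe_dump(
            {"width": spec.width, "height": spec.height, "cycle_ms": spec.schedule.cycle_ms},
            fh,
        )
    return written + [manifest_path, truth_path, meta]


def _stage_pair(params: dict, out: Path, seed: int) -> list[Path]:
    frames = acquisition.read_manifest(out / "frames.csv")
    result = acquisition.pair_frames(frames, params.get("max_gap_ms", 7.5))
    pairs_path = out / "pairs.csv"
    acquisition.pairs_to_frame(result.pairs).to_csv(pairs_path, index=False)
    rej_path = out / "pairing_rejections.csv"
    pd.DataFrame(
        [(f.index, f.illumination, reason) for f, reason in result.rejections],
        columns=["index", "illumination", "reason"],
    ).to_csv(rej_path, index=False)
    return [pairs_path, rej_path]


def _read_pairs(out: Path) -> list[acquisition.UVVisiblePair]:
    df = pd.read_csv(out / "pairs.csv")
    pairs = []
    for r in df.itertuples(index=False):
        uv = acquisition.FrameRecord(
            int(r.uv_index), float(r.uv_timestamp_ms), "uv", str(r.camera_id), str(r.uv_path)
        )
        vis = acquisition.FrameRecord(
            int(r.visible_index), float(r.visible_timestamp_ms), "visible",
            str(r.camera_id), str(r.visible_path),
        )
        pairs.append(acquisition.UVVisiblePair(uv=uv, visible=vis))
    return pairs


def _stage_serial_label(params: dict, out: Path, seed: int) -> list[Path]:
    pairs = _read_pairs(out)
    cfg = serial.DyeMaskConfig(**params)
    track, failures = serial.label_sequence(
        pairs, cfg, loader=lambda p: _load_image(out / p)
    )
    track_path = out / "track.csv"
    serial.write_track(track, track_path)
    if failures:
        logger.warning("%d frames failed during labeling", len(failures))
    return [track_path]


def _stage_export_labels(params: dict, out: Path, seed: int) -> list[Path]:
    with open(out / "fixture.yaml") as fh:
        meta = yaml.safe_load(fh)
    track = serial.read_track(out / "track.csv", meta["width"], meta["height"])
    name = params.get("landmark_name", "landmark")
    images = [
        {"id": str(l.frame_index), "file_name": "", "width": meta["width"], "height": meta["height"]}
        for l in track
    ]
    labels = {str(l.frame_index): {name: l} for l in track}
    path = out / "dataset.json"
    propagation.export_dataset(images, labels, [name], path)
    return [path]


def _stage_parallel_demo(params: dict, out: Path, seed: int) -> list[Path]:
    spec_kwargs = {
        k: params[k]
        for k in ("width", "height", "n_spots", "warp", "translation")
        if k in params
    }
    if "matrix" in params:
        spec_kwargs["matrix"] = tuple(tuple(row) for row in params["matrix"])
    if "translation" in spec_kwargs:
        spec_kwargs["translation"] = tuple(spec_kwargs["translation"])
    scene = gen_speckle_scene(SpeckleFixtureSpec(seed=seed, **spec_kwargs))
    contrast = params.get("contrast_threshold", barcode.DEFAULT_CONTRAST_THRESHOLD)
    template_fs = barcode.detect_features(scene.template, contrast, "template")
    target_fs = barcode.detect_features(scene.frames[0], contrast, "target")
    matches = barcode.coherency_filter(
        barcode.match_features(template_fs, target_fs),
        barcode.CoherencyConfig(
            params.get("delta_px", 50.0), params.get("epsilon_px", 50.0)
        ),
    )
    auto_cfg = propagation.AutoLandmarkConfig(
        min_spacing_px=params.get("min_spacing_px", 30.0),
        neighborhood_radius_px=params.get("neighborhood_radius_px", 30.0),
        min_neighbors=params.get("min_neighbors", 10),
        seed=seed,
    )
    landmarks = propagation.select_auto_landmarks(template_fs, auto_cfg)
    labels = propagation.propagate_frame(landmarks, matches, auto_cfg)
    rows = []
    corr = scene.correspondences[0]
    for i in landmarks.landmark_indices:
        l = labels[i]
        tx, ty = corr(template_fs.xy[i][None, :])[0]
        rows.append(
            {
                "landmark_index": i,
                "template_x": template_fs.xy[i, 0],
                "template_y": template_fs.xy[i, 1],
                "x": l.x,
                "y": l.y,
                "present": l.present,
                "source": l.source,
                "truth_x": tx,
                "truth_y": ty,
            }
        )
    path = out / "propagated_labels.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


_STAGE_FUNCS: dict[str, Callable[[dict, Path, int], list[Path]]] = {
    "simulate_serial": _stage_simulate_serial,
    "pair": _stage_pair,
    "serial_label": _stage_serial_label,
    "export_labels": _stage_export_labels,
    "parallel_demo": _stage_parallel_demo,
}


def run_pipeline(config: Mapping[str, Any], dry_run: bool = False) -> dict:
    """Execute the configured stages and return the artifact manifest.

    The manifest maps each output file (relative to ``out_dir``) to its
    SHA-256 hash.  A stage failure aborts with the stage name and the partial
    manifest attached to the raised :class:`StageError`.
    """
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(config["out_dir"])
    level = config.get("log_level", "INFO")
    logging.basicConfig(level=getattr(logging, str(level).upper(), logging.INFO))

    plan = [entry["stage"] for entry in config["stages"]]
    if dry_run:
        return {"plan": plan, "seed": seed, "files": {}}

    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"plan": plan, "seed": seed, "files": {}, "stages": []}
    for entry in config["stages"]:
        name = entry["stage"]
        params = dict(entry.get("params") or {})
        s = stage_seed(seed, name)
        logger.info("running stage %s (seed %d)", name, s)
        try:
            written = _STAGE_FUNCS[name](params, out, s)
        except Exception as exc:  # noqa: BLE001 - abort carries stage name
            err = StageError(name, str(exc))
            err.partial_manifest = manifest
            raise err from exc
        for path in written:
            manifest["files"][str(Path(path).relative_to(out))] = _sha256(Path(path))
        manifest["stages"].append({"stage": name, "seed": s})
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
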