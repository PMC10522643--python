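"""Strobed illumination schedules and UV/visible frame pairing.

The acquisition model captures the alternating UV / visible strobe cycle:
within each cycle the UV source excites the dye, a first shutter captures
the fluorescing scene, and a second shutter captures the visibly lit scene.
Labels computed from the UV frame are transferred to the *next* visible
frame, so the core operation here is pairing each UV frame with the
visible frame that immediately follows it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputOrderError, InvalidScheduleError

UV = "uv"
VISIBLE = "visible"

BIPHASIC = "biphasic"
TRIPHASIC = "triphasic"


@dataclass(frozen=True)
class TriggerSchedule:
    """Timing of one UV+visible strobe cycle, all quantities in milliseconds.

    ``uv_on`` and ``visible_on`` are half-open ``[start, stop)`` intervals.
    ``shutter_times_ms`` holds the UV-shutter and visible-shutter trigger
    instants, in that order.
    """

    cycle_ms: float
    scheme: str
    uv_on: tuple[float, float]
    visible_on: tuple[float, float]
    shutter_times_ms: tuple[float, float]
    exposure_ms: float

    @property
    def uv_shutter_ms(self) -> float:
        return self.shutter_times_ms[0]

    @property
    def visible_shutter_ms(self) -> float:
        return self.shutter_times_ms[1]

    @property
    def shutter_offset_ms(self) -> float:
        """Delay from UV capture to the subsequent visible capture."""
        return self.shutter_times_ms[1] - self.shutter_times_ms[0]

    def to_dict(self) -> dict:
        return {
            "cycle_ms": self.cycle_ms,
            "scheme": self.scheme,
            "uv_on": list(self.uv_on),
            "visible_on": list(self.visible_on),
            "shutter_times_ms": list(self.shutter_times_ms),
            "exposure_ms": self.exposure_ms,
        }


@dataclass(frozen=True)
class FrameRecord:
    """One captured frame in a per-camera stream."""

    index: int
    timestamp_ms: float
    illumination: str
    camera_id: str = "cam0"
    path: str = ""

    def __post_init__(self):
        if self.illumination not in (UV, VISIBLE):
            raise ValueError(f"unknown illumination {self.illumination!r}")


@dataclass(frozen=True)
class UVVisiblePair:
    """A UV frame and the visible frame that follows it."""

    uv: FrameRecord
    visible: FrameRecord

    @property
    def gap_ms(self) -> float:
        return self.visible.timestamp_ms - self.uv.timestamp_ms


@dataclass
class PairingResult:
    pairs: list[UVVisiblePair] = field(default_factory=list)
    rejections: list[tuple[FrameRecord, str]] = field(default_factory=list)


def build_trigger_schedule(
    cycle_ms: float,
    scheme: str,
    exposure_ms: float,
    uv_fraction: float = 0.5,
) -> TriggerSchedule:
    """Construct a strobe schedule for one capture cycle.

    The reference 10 ms cycle places the two shutters at the phase midpoints
    (2.5 ms and 7.5 ms); any other ``cycle_ms`` scales every instant
    proportionally.  Under the biphasic scheme the UV source stays on for the
    whole first half-cycle; under the triphasic scheme it is extinguished at
    ``uv_fraction * cycle_ms``, which must not run past the first shutter
    trigger (the UV image is exposed only by the decaying dye).

    Parameters
    ----------
    cycle_ms : float
        Duration of one UV+visible cycle.
    scheme : {"biphasic", "triphasic"}
    exposure_ms : float
        Shutter-open duration; must be shorter than half the cycle.
    uv_fraction : float
        Fraction of the cycle during which the UV source is on.  Ignored for
        the biphasic scheme (the UV phase is the first half-cycle).
    """
    if scheme not in (BIPHASIC, TRIPHASIC):
        raise InvalidScheduleError(f"unknown scheme {scheme!r}")
    if cycle_ms <= 0:
        raise InvalidScheduleError("cycle_ms must be positive")
    if not 0 < uv_fraction < 1:
        raise InvalidScheduleError("uv_fraction must lie in (0, 1)")
    if not 0 < exposure_ms < cycle_ms / 2:
        raise InvalidScheduleError(
            f"exposure {exposure_ms} ms does not fit in half of a "
            f"{cycle_ms} ms cycle"
        )

    half = cycle_ms / 2
    shutters = (cycle_ms / 4, 3 * cycle_ms / 4)
    visible_on = (half, cycle_ms)
    if scheme == BIPHASIC:
        uv_on = (0.0, half)
    else:
        uv_end = uv_fraction * cycle_ms
        if uv_end > shutters[0]:
            raise InvalidScheduleError(
                f"triphasic UV phase ends at {uv_end} ms, after the first "
                f"shutter trigger at {shutters[0]} ms"
            )
        uv_on = (0.0, uv_end)

    # both exposures must close before the next phase/cycle boundary
    if shutters[0] + exposure_ms > visible_on[0]:
        raise InvalidScheduleError("UV exposure runs into the visible phase")
    if shutters[1] + exposure_ms > cycle_ms:
        raise InvalidScheduleError("visible exposure runs past the cycle end")

    return TriggerSchedule(
        cycle_ms=cycle_ms,
        scheme=scheme,
        uv_on=uv_on,
        visible_on=visible_on,
        shutter_times_ms=shutters,
        exposure_ms=exposure_ms,
    )


def default_max_gap_ms(schedule: TriggerSchedule) -> float:
    """Pairing tolerance: 1.5x the schedule's shutter offset."""
    return 1.5 * schedule.shutter_offset_ms


def pair_frames(
    stream: Sequence[FrameRecord],
    max_gap_ms: float | None = None,
) -> PairingResult:
    """Pair each UV frame with the next visible frame of the same camera.

    Frames are grouped per camera.  Within a camera a UV frame pairs with the
    immediately following visible frame when the timestamp gap is positive and
    at most ``max_gap_ms``; every frame that ends up unpaired is logged with a
    reason.  Pairs never share a visible frame.

    If any frame carries a NaN timestamp, indices are used as surrogate
    timestamps with a warning and gap checks are skipped.
    """
    frames = list(stream)
    result = PairingResult()
    if not frames:
        return result

    check_gaps = max_gap_ms is not None
    if any(math.isnan(f.timestamp_ms) for f in frames):
        warnings.warn(
            "frames without timestamps: using indices, skipping gap checks",
            stacklevel=2,
        )
        frames = [
            FrameRecord(f.index, float(f.index), f.illumination, f.camera_id, f.path)
            for f in frames
        ]
        check_gaps = False

    by_camera: dict[str, list[FrameRecord]] = {}
    for f in frames:
        by_camera.setdefault(f.camera_id, []).append(f)

    for camera_frames in by_camera.values():
        ts = [f.timestamp_ms for f in camera_frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise InputOrderError(
                "stream must be strictly sorted by timestamp within a camera"
            )
        pending_uv: FrameRecord | None = None
        for f in camera_frames:
            if f.illumination == UV:
                if pending_uv is not None:
                    result.rejections.append((pending_uv, "no following visible"))
                pending_uv = f
            else:
                if pending_uv is None:
                    result.rejections.append((f, "no preceding UV"))
                    continue
                gap = f.timestamp_ms - pending_uv.timestamp_ms
                if check_gaps and gap > max_gap_ms:
                    result.rejections.append((pending_uv, "gap exceeds tolerance"))
                    result.rejections.append((f, "gap exceeds tolerance"))
                else:
                    result.pairs.append(UVVisiblePair(uv=pending_uv, visible=f))
                pending_uv = None
        if pending_uv is not None:
            result.rejections.append((pending_uv, "no following visible"))

    result.pairs.sort(key=lambda p: (p.uv.camera_id, p.uv.timestamp_ms))
    return result


# ---------------------------------------------------------------------------
# manifest I/O


MANIFEST_COLUMNS = ["index", "timestamp_ms", "illumination", "camera_id", "path"]


def frames_to_manifest(frames: Iterable[FrameRecord]) -> pd.DataFrame:
    rows = [
        (f.index, f.timestamp_ms, f.illumination, f.camera_id, f.path)
        for f in frames
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def manifest_to_frames(manifest: pd.DataFrame) -> list[FrameRecord]:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return [
        FrameRecord(
            index=int(r.index_),
            timestamp_ms=float(r.timestamp_ms),
            illumination=str(r.illumination),
            camera_id=str(r.camera_id),
            path="" if pd.isna(r.path) else str(r.path),
        )
        for r in manifest.rename(columns={"index": "index_"}).itertuples(index=False)
    ]


def read_manifest(path) -> list[FrameRecord]:
    return manifest_to_frames(pd.read_csv(path))


def write_manifest(frames: Iterable[FrameRecord], path) -> None:
    frames_to_manifest(frames).to_csv(path, index=False)


def pairs_to_frame(pairs: Iterable[UVVisiblePair]) -> pd.DataFrame:
    rows = [
        {
            "camera_id": p.uv.camera_id,
            "uv_index": p.uv.index,
            "uv_timestamp_ms": p.uv.timestamp_ms,
            "uv_path": p.uv.path,
            "visible_index": p.visible.index,
            "visible_timestamp_ms": p.visible.timestamp_ms,
            "visible_path": p.visible.path,
            "gap_ms": p.gap_ms,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "camera_id",
            "uv_index",
            "uv_timestamp_ms",
            "uv_path",
            "visible_index",
            "visible_timestamp_ms",
            "visible_path",
            "gap_ms",
        ],
    )
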