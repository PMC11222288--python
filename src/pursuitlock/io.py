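"""Core data types and file I/O.

Containers for the three recorded streams of a video-target detection
experiment — eye-gaze traces, multi-channel EEG, and per-trial target
annotations — plus readers/writers for their on-disk formats:

* gaze: delimited text with a ``time,x,y`` header (seconds, screen pixels);
* annotations: JSON sidecar per trial;
* EEG: a native bundle (``.npz`` array file + JSON metadata sidecar with
  channel labels, sampling rate, events and reference), with EDF import
  supported through :mod:`mne` for interoperability.

All times are seconds (float64) from recording start; EEG amplitudes are
microvolts; intervals are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to its documented format."""


class IntegrityError(ValueError):
    """Internally inconsistent data (e.g. label/row mismatch)."""


class UnsupportedFormatError(ValueError):
    """A container type this package cannot read."""


# --------------------------------------------------------------------------
# viewing geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ViewingGeometry:
    """Screen and observer geometry needed to convert pixels to visual angle.

    The angular velocity threshold separating saccades from slower eye
    movements is expressed in degrees of visual angle per second, so the
    physical screen size and viewing distance are required configuration.
    Defaults describe a 53 cm-wide (24", 16:9) display viewed at 60 cm.
    """

    screen_width_px: int = 1920
    screen_height_px: int = 1080
    screen_width_cm: float = 53.0
    screen_height_cm: float = 29.8
    viewing_distance_cm: float = 60.0

    def __post_init__(self) -> None:
        for name in ("screen_width_px", "screen_height_px", "screen_width_cm",
                     "screen_height_cm", "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"geometry field {name!r} must be positive")

    @property
    def cm_per_px_x(self) -> float:
        return self.screen_width_cm / self.screen_width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.screen_height_cm / self.screen_height_px

    def pixels_to_degrees(self, dx_px, dy_px):
        """Visual angle (degrees) subtended by a pixel displacement.

        Uses the chord angle ``2·atan(d / 2D)`` about the line of sight,
        which reduces to the small-angle approximation for foveal
        displacements.
        """
        d_cm = np.hypot(np.asarray(dx_px) * self.cm_per_px_x,
                        np.asarray(dy_px) * self.cm_per_px_y)
        return np.degrees(2.0 * np.arctan2(d_cm, 2.0 * self.viewing_distance_cm))

    def degrees_to_pixels(self, deg: float) -> float:
        """Horizontal pixel extent of a visual angle at screen centre."""
        d_cm = 2.0 * self.viewing_distance_cm * math.tan(math.radians(deg) / 2.0)
        return d_cm / self.cm_per_px_x


# --------------------------------------------------------------------------
# gaze
# --------------------------------------------------------------------------

@dataclass
class GazeTrace:
    """Timestamped screen-coordinate gaze samples (nominal 60 Hz).

    Coordinates may fall outside the screen (tracked but off-screen); such
    samples are flagged by :meth:`off_screen`, never dropped.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    geometry: ViewingGeometry
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.timestamps.shape == self.x.shape == self.y.shape):
            raise IntegrityError("timestamps, x and y must have equal length")
        if self.timestamps.size >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise IntegrityError("timestamps must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.timestamps.size

    def off_screen(self) -> np.ndarray:
        g = self.geometry
        return ((self.x < 0) | (self.x >= g.screen_width_px)
                | (self.y < 0) | (self.y >= g.screen_height_px))


def read_gaze_trace(path, geometry: ViewingGeometry,
                    sample_rate: float = 60.0) -> GazeTrace:
    """Read a delimited-text gaze file with a ``time,x,y`` header.

    Duplicate timestamps are collapsed keeping the first occurrence; time
    going backwards is a format error naming the offending data row
    (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise FormatError(f"{path}: cannot parse delimited text: {exc}") from exc
    missing = {"time", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time", "x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise FormatError(f"{path}: non-numeric value in column {col!r} "
                              f"at row {bad[0] + 1}")
        df[col] = vals
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    back = np.nonzero(dt < 0)[0]
    if back.size:
        raise FormatError(f"{path}: time goes backwards at row {back[0] + 2}")
    keep = np.ones(t.size, dtype=bool)
    keep[1:] = dt > 0  # drop exact duplicates, first occurrence kept
    return GazeTrace(t[keep], df["x"].to_numpy(float)[keep],
                     df["y"].to_numpy(float)[keep], geometry, sample_rate)


def write_gaze_trace(trace: GazeTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time": trace.timestamps, "x": trace.x, "y": trace.y}
                 ).to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# target annotations
# --------------------------------------------------------------------------

@dataclass
class TargetRegion:
    """Time-varying rectangular target region on screen.

    Sampled centre/half-extent trajectories; queries interpolate linearly
    and are defined on ``[onset_time, video_duration]``.
    """

    times: np.ndarray
    cx: np.ndarray
    cy: np.ndarray
    half_w: np.ndarray
    half_h: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "cx", "cy", "half_w", "half_h"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if any(getattr(self, k).size != n for k in ("cx", "cy", "half_w", "half_h")):
            raise IntegrityError("region trajectories must have equal length")

    def at(self, t):
        t = np.asarray(t, dtype=float)
        return (np.interp(t, self.times, self.cx),
                np.interp(t, self.times, self.cy),
                np.interp(t, self.times, self.half_w),
                np.interp(t, self.times, self.half_h))

    def contains(self, t, x, y, dilate_px: float = 0.0) -> np.ndarray:
        cx, cy, hw, hh = self.at(t)
        return ((np.abs(np.asarray(x) - cx) <= hw + dilate_px)
                & (np.abs(np.asarray(y) - cy) <= hh + dilate_px))


@dataclass
class TargetAnnotation:
    """Per-trial ground truth about the (at most one) video target."""

    trial_id: str
    has_target: bool
    video_duration: float = 20.0
    onset_time: float | None = None
    region: TargetRegion | None = None

    def __post_init__(self) -> None:
        if self.has_target:
            if self.onset_time is None or self.region is None:
                raise IntegrityError("target trials need onset_time and region")
            if not 0 <= self.onset_time <= self.video_duration:
                raise IntegrityError("onset_time outside video")
        else:
            if self.onset_time is not None or self.region is not None:
                raise IntegrityError(
                    "nontarget trials must not carry onset_time/region")


def write_annotation(annot: TargetAnnotation, path) -> Path:
    path = Path(path)
    obj = {"trial_id": annot.trial_id, "has_target": annot.has_target,
           "video_duration": annot.video_duration}
    if annot.has_target:
        r = annot.region
        obj["onset_time"] = annot.onset_time
        obj["region"] = {k: getattr(r, k).tolist()
                         for k in ("times", "cx", "cy", "half_w", "half_h")}
    path.write_text(json.dumps(obj))
    return path


def read_annotation(path) -> TargetAnnotation:
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    region = None
    if obj.get("has_target"):
        r = obj.get("region")
        if r is None:
            raise FormatError(f"{path}: target annotation without region")
        region = TargetRegion(**{k: np.asarray(r[k]) for k in
                                 ("times", "cx", "cy", "half_w", "half_h")})
    return TargetAnnotation(trial_id=str(obj["trial_id"]),
                            has_target=bool(obj["has_target"]),
                            video_duration=float(obj.get("video_duration", 20.0)),
                            onset_time=obj.get("onset_time"),
                            region=region)


# --------------------------------------------------------------------------
# EEG recordings
# --------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multi-channel EEG: ``channels × samples`` in microvolts.

    ``events`` are ``(time_s, code)`` pairs (e.g. the target-onset marker
    written by the trigger hardware); ``reference`` names the recording
    reference or ``"common-average"`` after re-referencing.
    """

    data: np.ndarray
    sample_rate: float
    channel_labels: Sequence[str]
    events: list[tuple[float, str]] = field(default_factory=list)
    reference: str = "CPz"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_labels = list(self.channel_labels)
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise IntegrityError("recording must have ≥1 channel and ≥1 sample")
        if self.data.shape[0] != len(self.channel_labels):
            raise IntegrityError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.events = [(float(t), str(c)) for t, c in self.events]
        for t, code in self.events:
            if not 0 <= t <= self.duration:
                raise IntegrityError(f"event {code!r} at {t} s outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy() if data is None else data,
            sample_rate=kw.get("sample_rate", self.sample_rate),
            channel_labels=list(kw.get("channel_labels", self.channel_labels)),
            events=list(kw.get("events", self.events)),
            reference=kw.get("reference", self.reference))

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


def _bundle_paths(path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    return path, path.with_suffix(".json")


def write_recording(rec: EEGRecording, path) -> Path:
    """Write the native bundle: ``<path>.npz`` plus a JSON metadata sidecar."""
    npz_path, side_path = _bundle_paths(path)
    np.savez(npz_path, data=rec.data)
    side = {"sample_rate": rec.sample_rate,
            "channel_labels": list(rec.channel_labels),
            "events": [[t, c] for t, c in rec.events],
            "reference": rec.reference}
    side_path.write_text(json.dumps(side))
    return npz_path


def read_recording(path) -> EEGRecording:
    """Read EEG from the native bundle or from an EDF(+) file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    if path.suffix == ".npz" or path.with_suffix(path.suffix + ".npz").exists():
        npz_path, side_path = _bundle_paths(path)
        if not npz_path.exists():
            raise FileNotFoundError(npz_path)
        if not side_path.exists():
            raise IntegrityError(f"bundle sidecar missing: {side_path}")
        with np.load(npz_path) as npz:
            data = npz["data"]
        side = json.loads(side_path.read_text())
        return EEGRecording(data=data, sample_rate=float(side["sample_rate"]),
                            channel_labels=side["channel_labels"],
                            events=[(float(t), str(c)) for t, c in side["events"]],
                            reference=side.get("reference", "unknown"))
    raise UnsupportedFormatError(f"{path}: not an EDF file or native bundle")


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    events = [(float(on), str(desc))
              for on, desc in zip(raw.annotations.onset,
                                  raw.annotations.description)]
    return EEGRecording(data=data_uv, sample_rate=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names), events=events,
                        reference="as-recorded")
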