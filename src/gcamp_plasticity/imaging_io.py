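"""I/O and ROI trace extraction for calcium-imaging movies.

Image stacks are multi-page grayscale TIFFs read as unsigned 16-bit and
converted to float on load.  ROI sets are a small JSON dialect with an
explicit coordinate convention (0-based, x = column, y = row).  Stimulus
protocols round-trip through YAML.  Tidy result tables go to CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml


class FormatError(ValueError):
    """Unreadable or out-of-contract input file."""


class GeometryError(ValueError):
    """ROI geometry incompatible with the image."""


class ValidationError(ValueError):
    """Inconsistent ROI set or protocol."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ImageStack:
    """A time series of grayscale frames (time x height x width, a.u.)."""

    frames: np.ndarray
    frame_interval_s: float

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise FormatError("stack must be 3-D with at least 2 frames")
        if not np.all(np.isfinite(frames)) or np.any(frames < 0):
            raise FormatError("intensities must be finite and non-negative")
        if self.frame_interval_s <= 0:
            raise FormatError("frame_interval_s must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_times(self) -> np.ndarray:
        """Mid-frame acquisition times in seconds."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval_s


@dataclass(frozen=True)
class ROI:
    """Circular region of interest.

    ``role`` is ``"cell"`` for an analyzed soma or ``"adjacent_control"``
    for a similar-sized region immediately beside a cell, used to detect
    out-of-focus contamination.  Controls name their cell via
    ``partner_id``.
    """

    id: str
    center_xy: tuple[float, float]
    radius_px: float
    role: str = "cell"
    partner_id: str = ""

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ValidationError(f"ROI {self.id}: radius must be positive")
        if self.role not in ("cell", "adjacent_control"):
            raise ValidationError(f"ROI {self.id}: unknown role {self.role!r}")
        if self.role == "adjacent_control" and not self.partner_id:
            raise ValidationError(
                f"ROI {self.id}: adjacent_control needs a partner_id")


@dataclass(frozen=True)
class FluorescenceTrace:
    """Per-frame mean fluorescence for one ROI (arbitrary units)."""

    values: np.ndarray
    frame_interval_s: float
    background: float = 0.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("trace values must be finite")
        if self.background < 0:
            raise ValidationError("background must be non-negative")
        if self.frame_interval_s <= 0:
            raise ValidationError("frame_interval_s must be positive")
        object.__setattr__(self, "values", values)

    def times(self) -> np.ndarray:
        return (np.arange(len(self.values)) + 0.5) * self.frame_interval_s


VALID_EVENT_KINDS = (
    "electrical_train", "mechanical", "high_K",
    "infusion_IS", "infusion_vehicle", "heat",
)


@dataclass(frozen=True)
class StimulusEvent:
    """One timed stimulus.

    ``params`` is kind-specific: ``frequency_Hz``/``n_pulses`` for
    electrical trains, ``force_mN`` for mechanical holds,
    ``top_temp_C``/``bottom_temp_C`` for heat.
    """

    kind: str
    onset_s: float
    duration_s: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in VALID_EVENT_KINDS:
            raise ValidationError(f"unknown stimulus kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.kind == "mechanical" and self.params.get("force_mN", 0) <= 0:
            raise ValidationError("mechanical events need force_mN > 0")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered stimulus events for one imaging session."""

    events: tuple[StimulusEvent, ...]
    session_label: str = ""

    def __post_init__(self):
        events = tuple(self.events)
        onsets = [e.onset_s for e in events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("event onsets must be strictly increasing")
        object.__setattr__(self, "events", events)

    def mechanical_forces(self) -> list[float]:
        return [e.params["force_mN"] for e in self.events
                if e.kind == "mechanical"]


# ---------------------------------------------------------------------------
# stacks


def read_stack(path, frame_interval_s: float = 0.05) -> ImageStack:
    """Read a multi-page grayscale TIFF as a float ImageStack."""
    try:
        with tifffile.TiffFile(path) as tif:
            photometric = tif.pages[0].photometric
            if photometric not in (tifffile.PHOTOMETRIC.MINISBLACK,
                                   tifffile.PHOTOMETRIC.MINISWHITE):
                raise FormatError(
                    f"stack must be grayscale, got {photometric.name}")
            frames = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise FormatError("stack needs at least 2 frames")
    if frames.ndim != 3:
        raise FormatError(
            f"expected grayscale time series, got shape {frames.shape}")
    return ImageStack(frames.astype(float), frame_interval_s)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as uint16 multi-page TIFF (values clipped to range)."""
    data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


# ---------------------------------------------------------------------------
# trace extraction


def roi_mask(roi: ROI, height: int, width: int) -> np.ndarray:
    """Boolean pixel-membership mask for a circular ROI.

    A pixel belongs to the ROI when its center (integer coordinates)
    lies within Euclidean distance ``radius_px`` of the ROI center.
    """
    cx, cy = roi.center_xy
    yy, xx = np.ogrid[:height, :width]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= roi.radius_px ** 2


def extract_trace(stack: ImageStack, roi: ROI,
                  background: float = 0.0) -> FluorescenceTrace:
    """Mean intensity inside the ROI disc at every frame."""
    _, h, w = stack.frames.shape
    mask = roi_mask(roi, h, w)
    if not mask.any():
        raise GeometryError(f"ROI {roi.id} covers no pixel of the image")
    values = stack.frames[:, mask].mean(axis=1)
    return FluorescenceTrace(values, stack.frame_interval_s, background)


def estimate_background(stack: ImageStack, fraction: float = 0.01) -> float:
    """Background level from the darkest pixels of the time-averaged image.

    Default is the mean of the darkest 1% of pixels of the temporal mean
    frame; pass a cell-free rectangle to :func:`extract_trace` instead if
    one is available.
    """
    mean_img = stack.frames.mean(axis=0).ravel()
    k = max(1, int(math.ceil(fraction * mean_img.size)))
    return float(np.sort(mean_img)[:k].mean())


# ---------------------------------------------------------------------------
# ROI sets

_COORD_CONVENTION = "0-based,x=col"


def read_roiset(path) -> list[ROI]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("coordinate_convention") != _COORD_CONVENTION:
        raise FormatError(
            f"ROI file must declare coordinate_convention "
            f"{_COORD_CONVENTION!r}")
    rois = [ROI(id=str(r["id"]), center_xy=(float(r["cx"]), float(r["cy"])),
                radius_px=float(r["r"]), role=r.get("role", "cell"),
                partner_id=str(r.get("partner_id", "") or ""))
            for r in doc["rois"]]
    validate_roiset(rois)
    return rois


def write_roiset(rois: Sequence[ROI], path) -> None:
    validate_roiset(rois)
    doc = {
        "coordinate_convention": _COORD_CONVENTION,
        "rois": [{"id": r.id, "cx": r.center_xy[0], "cy": r.center_xy[1],
                  "r": r.radius_px, "role": r.role,
                  "partner_id": r.partner_id} for r in rois],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def validate_roiset(rois: Sequence[ROI]) -> None:
    ids = [r.id for r in rois]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ROI ids")
    cells = {r.id for r in rois if r.role == "cell"}
    for r in rois:
        if r.role == "adjacent_control" and r.partner_id not in cells:
            raise ValidationError(
                f"adjacent_control {r.id} references missing cell "
                f"{r.partner_id!r}")


def control_for(rois: Sequence[ROI], cell_id: str) -> ROI | None:
    """The adjacent-control ROI flanking a cell, if one was drawn."""
    for r in rois:
        if r.role == "adjacent_control" and r.partner_id == cell_id:
            return r
    return None


# ---------------------------------------------------------------------------
# protocols


def _event_to_dict(e: StimulusEvent) -> dict:
    return {"kind": e.kind, "onset_s": e.onset_s,
            "duration_s": e.duration_s, "params": dict(e.params)}


def write_protocol(protocol: StimulusProtocol, path) -> None:
    doc = {"session_label": protocol.session_label,
           "events": [_event_to_dict(e) for e in protocol.events]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_protocol(path) -> StimulusProtocol:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    events = tuple(
        StimulusEvent(kind=e["kind"], onset_s=float(e["onset_s"]),
                      duration_s=float(e["duration_s"]),
                      params=dict(e.get("params") or {}))
        for e in doc.get("events", ()))
    return StimulusProtocol(events, doc.get("session_label", ""))


# ---------------------------------------------------------------------------
# result tables

RESULT_COLUMNS = ["cell_id", "session", "event_index", "kind", "param",
                  "peak_dff_pct", "t50_s", "responded"]


def write_results(table: pd.DataFrame, path) -> None:
    """Write a tidy result table (one row per cell x session x stimulus)."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing and len(table):
        raise ValidationError(f"result table missing columns {missing}")
    if not len(table):
        table = pd.DataFrame(columns=RESULT_COLUMNS)
    table.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
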