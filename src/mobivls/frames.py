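"""Reading and writing HDR thermal frames and tabular records.

Frames are raw thermal counts (14-bit sensor data carried in a 16-bit
container) stored losslessly as single-channel 16-bit PNG or TIFF.
Ground-truth and detection tables are comma-separated text with a header.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ThermalFrame",
    "GroundTruthRecord",
    "DetectionRecord",
    "FrameFormatError",
    "SchemaError",
    "read_frame",
    "write_frame",
    "read_ground_truth",
    "write_ground_truth",
    "read_detections",
    "write_detections",
]

OCCLUSION_STATES = ("visible", "partial", "full")

GT_COLUMNS = ("frame_id", "koala_id", "x", "y", "occlusion_state")
DET_COLUMNS = ("frame_id", "x", "y", "confidence")


class FrameFormatError(ValueError):
    """Raised for unreadable frames or frames violating the 16-bit contract."""


class SchemaError(ValueError):
    """Raised for malformed ground-truth or detection tables."""


@dataclasses.dataclass(frozen=True)
class ThermalFrame:
    """A single HDR thermal frame of raw counts.

    Parameters
    ----------
    pixels
        2-D array of non-negative integer counts, each in [0, 65535].
    frame_id
        Identifier, by convention the file stem.
    gain, offset
        Optional linear radiometric map ``temperature_C = gain*counts + offset``.
        Defaults to the identity; the camera transfer function is metadata only.
    """

    pixels: np.ndarray
    frame_id: str = ""
    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FrameFormatError(f"frame must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise FrameFormatError(f"frame counts must be integers, got {px.dtype}")
        if px.size and (px.min() < 0 or px.max() > 65535):
            raise FrameFormatError("counts must lie in [0, 65535]")
        object.__setattr__(self, "pixels", px.astype(np.uint16, copy=False))

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def to_celsius(self) -> np.ndarray:
        """Apply the linear radiometric map to the counts."""
        return self.gain * self.pixels.astype(np.float64) + self.offset


@dataclasses.dataclass(frozen=True)
class GroundTruthRecord:
    """One annotated animal location in one frame.

    Coordinates are 0-based with ``x`` the column and ``y`` the row index;
    sub-pixel centroids are allowed. ``occlusion_state`` is one of
    ``visible``, ``partial`` or ``full``; fully occluded records carry no
    thermal signature and are excluded from the positive set during scoring.
    """

    frame_id: str
    koala_id: str
    x: float
    y: float
    occlusion_state: str = "visible"

    def __post_init__(self) -> None:
        if self.occlusion_state not in OCCLUSION_STATES:
            raise SchemaError(
                f"unknown occlusion_state {self.occlusion_state!r}; "
                f"expected one of {OCCLUSION_STATES}"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise SchemaError("ground-truth coordinates must be finite")


@dataclasses.dataclass(frozen=True)
class DetectionRecord:
    """One detector output: a centroid and a confidence in [0, 1]."""

    frame_id: str
    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise SchemaError(f"confidence {self.confidence} outside [0, 1]")


# ---------------------------------------------------------------------------
# frame I/O


def read_frame(path: str | Path) -> ThermalFrame:
    """Read a single-channel 16-bit PNG or TIFF frame, bit-exactly.

    Raises :class:`FrameFormatError` for multi-channel input or any bit
    depth other than 16. Counts are never rescaled.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with format context
        raise FrameFormatError(f"cannot read frame {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FrameFormatError(
            f"{path}: expected single-channel image, got shape {arr.shape}"
        )
    if arr.dtype != np.uint16:
        raise FrameFormatError(f"{path}: expected 16-bit depth, got dtype {arr.dtype}")
    return ThermalFrame(pixels=arr, frame_id=path.stem)


def write_frame(frame: ThermalFrame, path: str | Path) -> Path:
    """Write a frame losslessly as 16-bit single-channel PNG or TIFF."""
    path = Path(path)
    iio.imwrite(path, frame.pixels.astype(np.uint16))
    return path


# ---------------------------------------------------------------------------
# tabular I/O


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_ground_truth(
    path: str | Path,
    width: int | None = None,
    height: int | None = None,
) -> list[GroundTruthRecord]:
    """Read a ground-truth CSV, validating coordinates and occlusion tokens.

    When ``width``/``height`` are given, coordinates are range-checked
    against them; schema errors report the offending (1-based data) row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, GT_COLUMNS, path)
    records: list[GroundTruthRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        x, y = float(row.x), float(row.y)
        state = str(row.occlusion_state)
        if state not in OCCLUSION_STATES:
            raise SchemaError(f"{path}: row {i}: unknown occlusion token {state!r}")
        if width is not None and not (0 <= x < width):
            raise SchemaError(f"{path}: row {i}: x={x} outside [0, {width})")
        if height is not None and not (0 <= y < height):
            raise SchemaError(f"{path}: row {i}: y={y} outside [0, {height})")
        records.append(
            GroundTruthRecord(
                frame_id=str(row.frame_id),
                koala_id=str(row.koala_id),
                x=x,
                y=y,
                occlusion_state=state,
            )
        )
    return records


def write_ground_truth(records: Iterable[GroundTruthRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=GT_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_detections(path: str | Path) -> list[DetectionRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, DET_COLUMNS, path)
    records: list[DetectionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        conf = float(row.confidence)
        if not 0.0 <= conf <= 1.0:
            raise SchemaError(f"{path}: row {i}: confidence {conf} outside [0, 1]")
        records.append(
            DetectionRecord(
                frame_id=str(row.frame_id), x=float(row.x), y=float(row.y), confidence=conf
            )
        )
    return records


def write_detections(records: Iterable[DetectionRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=DET_COLUMNS)
    df.to_csv(path, index=False)
    return path
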