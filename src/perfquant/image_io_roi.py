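"""Frame-stack IO, ROI definitions, and ROI time-intensity curve extraction.

Conventions (used everywhere, tested):
  * pixel coordinates are 0-based;
  * rectangles are half-open, ``[row0, row1) x [col0, col1)``;
  * frame index ``k`` maps to time ``origin_timestamp + k / frame_rate``;
    that mapping is owned by :class:`FrameStack` and never recomputed ad hoc.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import (
    ConfigurationError,
    CurveParseError,
    InvalidInputError,
    UnsupportedFormatError,
)

__all__ = [
    "FrameStack",
    "ROIDefinition",
    "TimeIntensityCurve",
    "read_frame_stack",
    "write_frame_stack",
    "extract_roi_curve",
    "read_curve_csv",
    "write_curve_csv",
    "read_roi_json",
    "write_roi_json",
]


@dataclass(frozen=True)
class FrameStack:
    """A T x H x W grayscale image sequence at a fixed frame rate."""

    frames: np.ndarray
    frame_rate: float
    bit_depth: int
    origin_timestamp: float = 0.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise InvalidInputError(
                f"frames must be T x H x W, got shape {frames.shape}"
            )
        if frames.shape[0] < 2:
            raise InvalidInputError("a frame stack needs at least 2 frames")
        if self.frame_rate <= 0:
            raise InvalidInputError("frame_rate must be positive")
        if self.bit_depth not in (8, 12, 16):
            raise InvalidInputError("bit_depth must be one of 8, 12, 16")
        if frames.min() < 0 or frames.max() > self.ceiling:
            raise InvalidInputError(
                f"intensities must lie in [0, {self.ceiling}] for "
                f"{self.bit_depth}-bit data"
            )

    @property
    def ceiling(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of every frame, in seconds."""
        return self.origin_timestamp + np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class ROIDefinition:
    """A named region: either a half-open rectangle or an explicit mask."""

    name: str
    rect: tuple[int, int, int, int] | None = None  # row0, col0, row1, col1
    mask: np.ndarray | None = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.mask is None):
            raise InvalidInputError("give exactly one of rect or mask")
        if self.rect is not None:
            r0, c0, r1, c1 = self.rect
            if not (0 <= r0 < r1 and 0 <= c0 < c1):
                raise InvalidInputError(f"empty or inverted rectangle {self.rect}")
        else:
            mask = np.asarray(self.mask, dtype=bool)
            object.__setattr__(self, "mask", mask)
            if mask.ndim != 2 or not mask.any():
                raise InvalidInputError("mask must be a nonempty 2-D boolean array")

    def to_mask(self, height: int, width: int) -> np.ndarray:
        """Render the ROI as a boolean H x W mask, checking bounds."""
        if self.mask is not None:
            if self.mask.shape != (height, width):
                raise InvalidInputError(
                    f"mask shape {self.mask.shape} != frame shape {(height, width)}"
                )
            return self.mask
        r0, c0, r1, c1 = self.rect
        if r1 > height or c1 > width:
            raise InvalidInputError(
                f"rectangle {self.rect} exceeds frame shape {(height, width)}"
            )
        mask = np.zeros((height, width), dtype=bool)
        mask[r0:r1, c0:c1] = True
        return mask


@dataclass
class TimeIntensityCurve:
    """Per-ROI mean fluorescence intensity versus time.

    ``ceiling`` (the bit-depth maximum, when known) and ``saturation_fraction``
    (per-frame fraction of saturated pixels, when extracted from images) are
    carried along for downstream QC flagging.
    """

    times: np.ndarray
    intensities: np.ndarray
    injection_time: float
    roi_name: str = ""
    state_label: str = ""
    ceiling: float | None = None
    saturation_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise InvalidInputError("times and intensities must be equal-length 1-D")
        if self.times.size < 2:
            raise InvalidInputError("a curve needs at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if not (self.times[0] <= self.injection_time <= self.times[-1]):
            raise InvalidInputError(
                f"injection_time {self.injection_time} outside recording "
                f"[{self.times[0]}, {self.times[-1]}]"
            )

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    def with_intensities(self, intensities: np.ndarray) -> "TimeIntensityCurve":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


# --------------------------------------------------------------------- TIFF


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a multi-page grayscale TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    tifffile.imwrite(path, stack.frames.astype(dtype), photometric="minisblack")
    meta = {
        "frame_rate": stack.frame_rate,
        "bit_depth": stack.bit_depth,
        "origin_timestamp": stack.origin_timestamp,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_frame_stack(
    path: str | Path,
    frame_rate: float | None = None,
    bit_depth: int | None = None,
    origin_timestamp: float | None = None,
) -> FrameStack:
    """Read a multi-page grayscale TIFF into a :class:`FrameStack`.

    Acquisition metadata comes from the ``<name>.json`` sidecar if present;
    explicit arguments override it.  A missing frame rate is a configuration
    error, multi-sample (RGB) files are unsupported.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise UnsupportedFormatError(
                f"{path}: expected single-channel grayscale, got "
                f"{page.samplesperpixel} samples per pixel"
            )
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise UnsupportedFormatError(f"{path}: cannot interpret shape {frames.shape}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if frame_rate is None:
        frame_rate = meta.get("frame_rate")
    if frame_rate is None:
        raise ConfigurationError(
            f"{path}: frame rate not in sidecar metadata; pass frame_rate="
        )
    if bit_depth is None:
        bit_depth = meta.get("bit_depth")
    if bit_depth is None:
        bit_depth = {np.uint8: 8, np.uint16: 16}.get(frames.dtype.type, 16)
    if origin_timestamp is None:
        origin_timestamp = meta.get("origin_timestamp", 0.0)
    if frames.shape[0] < 2:
        raise InvalidInputError(f"{path}: a frame stack needs at least 2 frames")
    return FrameStack(
        frames=frames,
        frame_rate=float(frame_rate),
        bit_depth=int(bit_depth),
        origin_timestamp=float(origin_timestamp),
    )


# ---------------------------------------------------------------- extraction


def extract_roi_curve(
    stack: FrameStack,
    roi: ROIDefinition,
    injection_time: float,
    state_label: str = "",
) -> TimeIntensityCurve:
    """Mean intensity of the masked pixels in every frame.

    Saturated pixels (at the bit-depth ceiling) are included in the mean but
    their per-frame fraction is recorded on the curve for downstream QC.
    """
    _, height, width = stack.frames.shape
    mask = roi.to_mask(height, width)
    pixels = stack.frames[:, mask].astype(float)
    means = pixels.mean(axis=1)
    saturation = (pixels >= stack.ceiling).mean(axis=1)
    return TimeIntensityCurve(
        times=stack.times,
        intensities=means,
        injection_time=injection_time,
        roi_name=roi.name,
        state_label=state_label,
        ceiling=float(stack.ceiling),
        saturation_fraction=saturation,
    )


# ----------------------------------------------------------------------- CSV


def write_curve_csv(curve: TimeIntensityCurve, path: str | Path) -> Path:
    """Write ``time_s,intensity`` rows at full float precision."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("time_s,intensity\n")
        for t, v in zip(curve.times, curve.intensities):
            fh.write(f"{float(t)!r},{float(v)!r}\n")
    return path


def read_curve_csv(
    path: str | Path,
    injection_time: float,
    frame_rate: float | None = None,
    roi_name: str = "",
    state_label: str = "",
    ceiling: float | None = None,
) -> TimeIntensityCurve:
    """Read a two-column curve CSV; malformed rows raise with their number."""
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:
                if [c.strip() for c in row] != ["time_s", "intensity"]:
                    raise CurveParseError(
                        f"{path}: row 1: expected header 'time_s,intensity', "
                        f"got {row!r}"
                    )
                continue
            if len(row) != 2:
                raise CurveParseError(
                    f"{path}: row {lineno}: expected 2 columns, got {len(row)}"
                )
            try:
                times.append(float(row[0]))
                values.append(float(row[1]))
            except ValueError as exc:
                raise CurveParseError(
                    f"{path}: row {lineno}: non-numeric cell in {row!r}"
                ) from exc
    curve = TimeIntensityCurve(
        times=np.array(times),
        intensities=np.array(values),
        injection_time=injection_time,
        roi_name=roi_name,
        state_label=state_label,
        ceiling=ceiling,
    )
    if frame_rate is not None:
        dt = np.diff(curve.times)
        if not np.allclose(dt, 1.0 / frame_rate, rtol=1e-6, atol=1e-9):
            raise CurveParseError(
                f"{path}: sample spacing inconsistent with frame rate {frame_rate}"
            )
    return curve


# ------------------------------------------------------------------ ROI JSON


def write_roi_json(rois: list[ROIDefinition], path: str | Path) -> Path:
    path = Path(path)
    payload = []
    for roi in rois:
        if roi.rect is None:
            raise InvalidInputError(
                f"ROI {roi.name}: only rectangle ROIs are JSON-serializable"
            )
        payload.append(
            {
                "name": roi.name,
                "rect": list(roi.rect),
                "is_reference": roi.is_reference,
            }
        )
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_roi_json(path: str | Path) -> list[ROIDefinition]:
    entries = json.loads(Path(path).read_text())
    rois = [
        ROIDefinition(
            name=e["name"],
            rect=tuple(e["rect"]),
            is_reference=bool(e.get("is_reference", False)),
        )
        for e in entries
    ]
    if sum(r.is_reference for r in rois) != 1:
        raise ConfigurationError(
            f"{path}: exactly one ROI must have is_reference=true"
        )
    return rois
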