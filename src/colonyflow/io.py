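"""Image-sequence, mask, flow-field and result I/O plus acquisition calibration.

Frames are held as a single ``(T, H, W)`` float array normalized to [0, 1]
so that downstream segmentation parameters are independent of the source
bit depth.  Directory inputs are ordered by natural sort of the file names,
matching numbered exports from microscope time-lapse software.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "CalibrationProfile",
    "FrameSequence",
    "FlowField",
    "read_sequence",
    "expected_frame_count",
    "write_results",
    "read_results",
    "write_mask",
    "read_mask",
    "write_flow",
    "read_flow",
    "render_vector_overlay",
]


@dataclass(frozen=True)
class CalibrationProfile:
    """Physical scale of an acquisition.

    Parameters
    ----------
    microns_per_pixel : float
        Lateral scale of the objective/camera combination, μm per pixel.
        Must be supplied by the user; there is no meaningful default.
    minutes_per_frame : float
        Acquisition interval in minutes (8 min in the reference protocol).
    label : str
        Free-text description of the objective / instrument.
    """

    microns_per_pixel: float
    minutes_per_frame: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0):
            raise ValueError("microns_per_pixel must be > 0")
        if not (self.minutes_per_frame > 0):
            raise ValueError("minutes_per_frame must be > 0")

    @property
    def um_per_hour_factor(self) -> float:
        """Conversion factor from px/frame to μm/h."""
        return self.microns_per_pixel * (60.0 / self.minutes_per_frame)

    @classmethod
    def from_file(cls, path: str | Path) -> "CalibrationProfile":
        """Read a ``key=value`` calibration file.

        Recognized keys: ``microns_per_pixel``, ``minutes_per_frame``,
        ``label``.  Lines starting with ``#`` are ignored.
        """
        values: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed calibration line: {raw!r}")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        try:
            return cls(
                microns_per_pixel=float(values["microns_per_pixel"]),
                minutes_per_frame=float(values["minutes_per_frame"]),
                label=values.get("label", ""),
            )
        except KeyError as exc:
            raise ValueError(f"calibration file missing key: {exc}") from exc


@dataclass
class FrameSequence:
    """Ordered, equal-shape grayscale frames with optional calibration."""

    frames: np.ndarray  # (T, H, W) float in [0, 1]
    calibration: CalibrationProfile | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def __len__(self) -> int:
        return self.frame_count

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, idx):
        return self.frames[idx]


@dataclass
class FlowField:
    """Per-pixel displacement between two consecutive frames, px/frame.

    ``u`` is the column (x) displacement, ``v`` the row (y) displacement,
    row-major with origin at the top-left.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError("u and v must be 2-D arrays of identical shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flow components must be finite")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def _natural_key(name: str) -> tuple:
    return tuple(
        int(part) if part.isdigit() else part.lower()
        for part in re.split(r"(\d+)", name)
    )


def _to_gray01(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 3:
        if img.shape[-1] == 4:  # drop alpha
            img = img[..., :3]
        if img.shape[-1] == 3:
            # ITU-R 709 luminance, as used by skimage.color.rgb2gray
            img = img @ np.array([0.2125, 0.7154, 0.0721])
        else:
            raise ValueError(f"unsupported channel count: {img.shape[-1]}")
    elif img.ndim != 2:
        raise ValueError(f"expected 2-D frame, got ndim={img.ndim}")
    return img.astype(float)


def _normalize_stack(frames: list[np.ndarray], src_dtype: np.dtype) -> np.ndarray:
    stack = np.stack(frames).astype(float)
    if np.issubdtype(src_dtype, np.integer):
        stack /= float(np.iinfo(src_dtype).max)
    else:
        # float sources are assumed already on a [0, 1]-like scale;
        # rescale only if clearly outside it
        peak = np.max(np.abs(stack)) if stack.size else 1.0
        if peak > 1.0:
            stack /= peak
    return np.clip(stack, 0.0, 1.0)


def read_sequence(
    path: str | Path,
    pattern: str | None = None,
    calibration: CalibrationProfile | None = None,
) -> FrameSequence:
    """Read a time-lapse sequence from a multi-page TIFF or a frame directory.

    Parameters
    ----------
    path : path
        Multi-page TIFF file, or a directory containing numbered
        single-frame TIFF/PNG files.
    pattern : str, optional
        Glob restricting which files in a directory are read
        (e.g. ``"frame_*.tif"``).  Ignored for a single-file input.
    calibration : CalibrationProfile, optional
        Attached to the returned sequence for downstream unit conversion.

    Returns
    -------
    FrameSequence
        Frames in acquisition (page or natural-sort) order, single-channel
        float grayscale in [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    raw_frames: list[np.ndarray] = []
    src_dtype: np.dtype | None = None
    if path.is_dir():
        names = [
            p
            for p in path.iterdir()
            if p.is_file()
            and p.suffix.lower() in _IMAGE_SUFFIXES
            and (pattern is None or p.match(pattern))
        ]
        if not names:
            raise FileNotFoundError(f"no image frames found in {path}")
        names.sort(key=lambda p: _natural_key(p.name))
        for p in names:
            img = iio.imread(p)
            if src_dtype is None:
                src_dtype = np.asarray(img).dtype
            raw_frames.append(_to_gray01(img))
    else:
        pages = tifffile.imread(path)
        pages = np.asarray(pages)
        src_dtype = pages.dtype
        if pages.ndim == 2:
            raw_frames = [_to_gray01(pages)]
        elif pages.ndim == 3 and pages.shape[-1] in (3, 4):
            raw_frames = [_to_gray01(pages)]
        else:
            raw_frames = [_to_gray01(page) for page in pages]

    if len(raw_frames) < 2:
        raise ValueError(
            f"sequence at {path} has {len(raw_frames)} frame(s); at least 2 required"
        )
    shapes = {f.shape for f in raw_frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
    stack = _normalize_stack(raw_frames, src_dtype)
    return FrameSequence(frames=stack, calibration=calibration)


def expected_frame_count(duration_minutes: float, interval_minutes: float) -> int:
    """Number of frames captured over ``duration_minutes`` at a fixed interval.

    Both endpoints are imaged, so 4 h at 8-min intervals yields
    ``floor(240 / 8) + 1 = 31`` frames.
    """
    if interval_minutes <= 0:
        raise ValueError("interval must be positive")
    if duration_minutes < 0:
        raise ValueError("duration must be non-negative")
    return int(np.floor(duration_minutes / interval_minutes)) + 1


def write_results(record, path: str | Path) -> Path:
    """Write a motion record to CSV: one row per frame pair plus a summary row.

    Columns: pair index, MS in px/frame, MS in μm/h, growth percentage of the
    pair's first frame.  The final row carries the MMS.  Values are written
    in full ``repr`` precision so a round-trip read reproduces them exactly.
    """
    if record is None or len(record.ms_series_um_per_h) == 0:
        raise ValueError("cannot write an empty motion record")
    path = Path(path)
    growth = list(record.growth_series) if record.growth_series is not None else []
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["pair_index", "ms_px_per_frame", "ms_um_per_h", "growth_percent"]
        )
        for i, (ms_px, ms_um) in enumerate(
            zip(record.ms_series_px_per_frame, record.ms_series_um_per_h)
        ):
            g = growth[i] if i < len(growth) else ""
            writer.writerow([i, repr(float(ms_px)), repr(float(ms_um)),
                             repr(float(g)) if g != "" else ""])
        writer.writerow(["MMS", "", repr(float(record.mms)), ""])
    return path


def read_results(path: str | Path):
    """Read back a CSV written by :func:`write_results`.

    Returns
    -------
    (ms_px, ms_um, growth, mms) : tuple of lists / float
    """
    ms_px: list[float] = []
    ms_um: list[float] = []
    growth: list[float] = []
    mms = float("nan")
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        for row in reader:
            if row[0] == "MMS":
                mms = float(row[2])
                continue
            ms_px.append(float(row[1]))
            ms_um.append(float(row[2]))
            if row[3] != "":
                growth.append(float(row[3]))
    return ms_px, ms_um, growth, mms


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as 8-bit single-channel PNG/TIFF (cell=255)."""
    path = Path(path)
    out = (np.asarray(mask) > 0).astype(np.uint8) * 255
    iio.imwrite(path, out)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back to 0/1 uint8."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return (img > 127).astype(np.uint8)


def write_flow(flow: FlowField, path: str | Path) -> Path:
    """Write a flow field as a 2-plane 32-bit TIFF (plane 0 = u, 1 = v)."""
    path = Path(path)
    tifffile.imwrite(path, np.stack([flow.u, flow.v]).astype(np.float32))
    return path


def read_flow(path: str | Path) -> FlowField:
    planes = tifffile.imread(path)
    return FlowField(u=planes[0].astype(float), v=planes[1].astype(float))


def render_vector_overlay(
    frame: np.ndarray,
    flow: FlowField,
    mask: np.ndarray,
    stride: int = 16,
    scale: float = 4.0,
    color: tuple[int, int, int] = (255, 48, 48),
) -> np.ndarray:
    """Draw displacement arrows on a frame at every ``stride``-th masked pixel.

    Arrow (shaft) length is proportional to the displacement magnitude
    (``scale`` px drawn per px/frame).  Intended for visual QC of the flow
    field, mirroring vector-overlay figures from time-lapse viewers.

    Returns an ``(H, W, 3)`` uint8 RGB image.
    """
    from skimage.draw import line as _line

    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask)
    if frame.shape != flow.u.shape or frame.shape != mask.shape:
        raise ValueError("frame, flow and mask shapes must agree")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    lo, hi = float(frame.min()), float(frame.max())
    norm = (frame - lo) / (hi - lo) if hi > lo else np.zeros_like(frame)
    rgb = np.repeat((norm * 255).astype(np.uint8)[..., None], 3, axis=2)
    h, w = frame.shape
    for r in range(0, h, stride):
        for c in range(0, w, stride):
            if not mask[r, c]:
                continue
            dr = int(round(flow.v[r, c] * scale))
            dc = int(round(flow.u[r, c] * scale))
            r1 = int(np.clip(r + dr, 0, h - 1))
            c1 = int(np.clip(c + dc, 0, w - 1))
            rr, cc = _line(r, c, r1, c1)
            rgb[rr, cc] = color
    return rgb
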