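"""Physical motion indices of a culture: MS series, MMS and the start check.

MS (motion speed) is the mean optical-flow displacement magnitude over the
segmented cell area of one consecutive frame pair, converted to μm/h via
the acquisition calibration.  MMS (mean motion speed) averages the MS
values of a capture and is the per-location motion index; the per-sample
index averages MMS over the (typically five) imaged locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .flow import EmptyMaskError, FlowParams, dense_flow, masked_mean_magnitude
from .io import CalibrationProfile, FrameSequence

__all__ = [
    "MotionRecord",
    "StartConditionReport",
    "px_per_frame_to_um_per_hour",
    "ms_series",
    "mms",
    "aggregate_sample_mms",
    "compute_motion_record",
    "start_condition_check",
]


def px_per_frame_to_um_per_hour(value: float, calib: CalibrationProfile) -> float:
    """Convert a speed in px/frame to μm/h.

    ``value × microns_per_pixel × (60 / minutes_per_frame)``; e.g.
    1 px/frame at 0.5 μm/px and 8 min/frame is 3.75 μm/h.
    """
    if value < 0:
        raise ValueError("speed must be >= 0")
    return value * calib.um_per_hour_factor


@dataclass
class MotionRecord:
    """Per-pair motion speeds and their capture-level summary.

    ``ms_series_um_per_h`` holds one MS per consecutive frame pair
    (``n_frames - 1`` entries); pairs whose mask was empty are NaN and are
    excluded from the MMS.
    """

    ms_series_px_per_frame: np.ndarray
    ms_series_um_per_h: np.ndarray
    mms: float
    growth_series: np.ndarray | None
    calibration: CalibrationProfile
    n_frames: int
    frame_count_divisor: bool = False

    def __post_init__(self) -> None:
        self.ms_series_px_per_frame = np.asarray(self.ms_series_px_per_frame, float)
        self.ms_series_um_per_h = np.asarray(self.ms_series_um_per_h, float)
        if len(self.ms_series_um_per_h) != self.n_frames - 1:
            raise ValueError("ms_series must have n_frames - 1 entries")


def ms_series(
    seq: FrameSequence,
    masks,
    flow_params: FlowParams | None = None,
    calib: CalibrationProfile | None = None,
) -> np.ndarray:
    """MS (μm/h) for every consecutive frame pair of a sequence.

    The mask of the pair's first frame delimits the cell area (vectors
    originate there).  A pair with an empty mask yields NaN with a
    warning; callers exclude NaNs from the MMS.

    Returns an array of length ``frame_count - 1``.
    """
    calib = calib or seq.calibration
    if calib is None:
        raise ValueError("a CalibrationProfile is required (none attached)")
    masks = list(masks)
    if len(masks) != seq.frame_count:
        raise ValueError("need one mask per frame")
    out = np.empty(seq.frame_count - 1)
    for i in range(seq.frame_count - 1):
        flow = dense_flow(seq.frames[i], seq.frames[i + 1], flow_params)
        try:
            ms_px = masked_mean_magnitude(flow, masks[i])
        except EmptyMaskError:
            warnings.warn(
                f"frame pair {i}: empty cell mask, MS recorded as missing"
            )
            out[i] = np.nan
            continue
        out[i] = px_per_frame_to_um_per_hour(ms_px, calib)
    return out


def mms(series, frame_count_divisor: bool = False, n_frames: int | None = None) -> float:
    """Mean motion speed of a capture, μm/h.

    By default the arithmetic mean over the available (non-missing) MS
    values, i.e. over the actual frame-pair count.  With
    ``frame_count_divisor=True`` the pair sum is divided by ``n_frames``
    (pair count + 1) instead, matching the published description of the
    divisor; the two differ by the fixed ratio (n−1)/n, about 30/31 for
    the 4-h schedule.
    """
    series = np.asarray(list(series), dtype=float)
    if series.size == 0:
        raise ValueError("MS series is empty")
    valid = series[~np.isnan(series)]
    if valid.size == 0:
        raise ValueError("MS series has no non-missing values")
    if frame_count_divisor:
        if n_frames is None:
            n_frames = series.size + 1
        return float(valid.sum() / n_frames)
    return float(valid.mean())


def aggregate_sample_mms(location_mms) -> float:
    """Per-sample MMS: mean of the per-location MMS values.

    The reference protocol images five randomly-chosen locations per dish
    and represents the sample by their mean.
    """
    values = np.asarray(list(location_mms), dtype=float)
    if values.size == 0:
        raise ValueError("no location MMS values")
    return float(values.mean())


def compute_motion_record(
    seq: FrameSequence,
    masks,
    flow_params: FlowParams | None = None,
    calib: CalibrationProfile | None = None,
    frame_count_divisor: bool = False,
) -> MotionRecord:
    """Full per-capture motion record: MS series, MMS and growth series."""
    from .segmentation import growth_series as _growth

    calib = calib or seq.calibration
    if calib is None:
        raise ValueError("a CalibrationProfile is required (none attached)")
    series_um = ms_series(seq, masks, flow_params, calib)
    series_px = series_um / calib.um_per_hour_factor
    return MotionRecord(
        ms_series_px_per_frame=series_px,
        ms_series_um_per_h=series_um,
        mms=mms(series_um, frame_count_divisor=frame_count_divisor, n_frames=seq.frame_count),
        growth_series=np.asarray(_growth(masks)),
        calibration=calib,
        n_frames=seq.frame_count,
        frame_count_divisor=frame_count_divisor,
    )


@dataclass
class StartConditionReport:
    """Diagnostics of the capture start-condition check."""

    passed: bool
    start_growth_percent: float
    relative_change: float
    band: tuple[float, float]
    max_relative_change: float
    messages: list[str] = field(default_factory=list)


def start_condition_check(
    growth,
    band: tuple[float, float] = (40.0, 60.0),
    max_relative_change: float = 0.10,
) -> StartConditionReport:
    """Check that a capture started near 50% confluency and stayed flat.

    Captures started too dense (≥ ~70%) show declining motion from contact
    inhibition, and too sparse (~30%) show rising motion, so the motion
    index is only representative when the capture starts around 50%
    confluency and overall growth barely changes during it.

    Parameters
    ----------
    growth : sequence of per-frame growth percentages
    band : (low, high)
        Acceptable first-frame growth window, percent (default 40–60).
    max_relative_change : float
        Maximum |relative change| of the series across the capture.

    Returns
    -------
    StartConditionReport
        ``passed`` is True only if both checks hold; the report always
        carries the measured values.
    """
    growth = np.asarray(list(growth), dtype=float)
    if growth.size == 0:
        raise ValueError("growth series is empty")
    start = float(growth[0])
    if start > 0:
        rel = float((growth.max() - growth.min()) / start)
    else:
        rel = np.inf if growth.max() > 0 else 0.0
    messages = []
    in_band = band[0] <= start <= band[1]
    flat = rel <= max_relative_change
    if not in_band:
        messages.append(
            f"start growth {start:.1f}% outside the {band[0]:.0f}-{band[1]:.0f}% band"
        )
    if not flat:
        messages.append(
            f"growth changed by {100 * rel:.1f}% of start during capture "
            f"(limit {100 * max_relative_change:.0f}%)"
        )
    return StartConditionReport(
        passed=in_band and flat,
        start_growth_percent=start,
        relative_change=rel,
        band=band,
        max_relative_change=max_relative_change,
        messages=messages,
    )
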