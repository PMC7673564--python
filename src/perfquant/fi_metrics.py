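"""Quantitative perfusion parameters from a ROI time-intensity curve.

Three parameters are extracted from each curve:

* **BSFI** - peak intensity during the first passage of the dye (the bounded
  post-injection analysis window) minus the pre-injection baseline mean.
  Baseline subtraction removes the residual-dye offset that builds up over
  repeated injections.
* **SFI** - maximal rising slope between bolus onset and peak, estimated by
  sliding-window least squares (raw adjacent-frame differences are noise-
  dominated on 8-bit data; a 2-frame window reduces to finite differences).
* **TTS** - delay from injection to the first detectable signal rise,
  reported both absolutely and as a ratio to the reference ROI.

Onset detection is two-stage: a robust threshold crossing (baseline mean +
k*sd sustained for m frames) locates the rise, then a walk-back refinement
returns the first frame actually above the baseline level, so that on clean
data the reported onset matches the true arrival to within one frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import defaults
from .errors import InvalidInputError, UnusableCurveError
from .image_io_roi import TimeIntensityCurve

__all__ = [
    "MetricParams",
    "BaselineStats",
    "FIMetricsResult",
    "baseline_statistics",
    "smooth_curve",
    "detect_onset",
    "compute_bsfi",
    "compute_sfi",
    "compute_tts_ratio",
    "analyze_curve",
]

_EPS = 1e-9


@dataclass(frozen=True)
class MetricParams:
    """All analysis knobs in one place; logged into every result."""

    baseline_window: float = defaults.BASELINE_WINDOW
    smooth_half_width: int = defaults.SMOOTH_HALF_WIDTH
    onset_k: float = defaults.ONSET_K
    onset_m: int = defaults.ONSET_M
    sd_floor: float = defaults.SD_FLOOR
    onset_refine_margin: float = defaults.ONSET_REFINE_MARGIN
    slope_window: int = defaults.SLOPE_WINDOW
    analysis_window: float = defaults.ANALYSIS_WINDOW
    saturation_flag_fraction: float = defaults.SATURATION_FLAG_FRACTION

    def __post_init__(self) -> None:
        if self.onset_k <= 0 or self.onset_m < 1:
            raise InvalidInputError("need onset_k > 0 and onset_m >= 1")
        if self.slope_window < 2:
            raise InvalidInputError("slope_window must span >= 2 frames")
        if self.smooth_half_width < 0:
            raise InvalidInputError("smooth_half_width must be >= 0")


@dataclass(frozen=True)
class BaselineStats:
    mean: float
    sd: float
    window: tuple[float, float]  # [t_start, t_end) in seconds
    n_frames: int
    short: bool = False          # True when the requested window was truncated


@dataclass
class FIMetricsResult:
    roi_name: str
    state_label: str
    bsfi: float
    sfi: float
    tts: float
    onset_time: float
    peak_time: float
    peak_value: float
    baseline_mean: float
    baseline_sd: float
    tts_ratio: float = float("nan")
    flags: set[str] = field(default_factory=set)
    params: dict = field(default_factory=dict)


# ------------------------------------------------------------------ baseline


def baseline_statistics(
    curve: TimeIntensityCurve, window_length: float = defaults.BASELINE_WINDOW
) -> BaselineStats:
    """Mean and sample sd over the pre-injection window.

    The window is ``[injection - window_length, injection)``; if the
    recording starts later than that, the available span is used and the
    result is marked short (fewer than 5 frames also counts as short).
    """
    t0 = curve.injection_time - window_length
    sel = (curve.times >= t0 - _EPS) & (curve.times < curve.injection_time)
    n = int(sel.sum())
    if n == 0:
        raise UnusableCurveError(
            f"{curve.roi_name or 'curve'}: no frames before injection at "
            f"t={curve.injection_time}"
        )
    short = (curve.times[0] > t0 + _EPS) or (n < 5)
    vals = curve.intensities[sel]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return BaselineStats(
        mean=mean,
        sd=sd,
        window=(float(max(t0, curve.times[0])), float(curve.injection_time)),
        n_frames=n,
        short=short,
    )


# ----------------------------------------------------------------- smoothing


def smooth_curve(
    curve: TimeIntensityCurve, half_width: int = defaults.SMOOTH_HALF_WIDTH
) -> TimeIntensityCurve:
    """Centered moving average of width ``2*half_width + 1``, truncated at
    the ends; ``half_width=0`` is the identity."""
    if half_width < 0:
        raise InvalidInputError("half_width must be >= 0")
    if half_width == 0:
        return curve
    y = curve.intensities
    n = y.size
    csum = np.concatenate(([0.0], np.cumsum(y)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_width, 0)
    hi = np.minimum(idx + half_width + 1, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return curve.with_intensities(smoothed)


# --------------------------------------------------------------------- onset


def detect_onset(
    curve: TimeIntensityCurve,
    baseline: BaselineStats,
    k: float = defaults.ONSET_K,
    m: int = defaults.ONSET_M,
    sd_floor: float = defaults.SD_FLOOR,
    refine_margin: float = defaults.ONSET_REFINE_MARGIN,
    analysis_window: float = defaults.ANALYSIS_WINDOW,
) -> Optional[float]:
    """Time of the first detectable rise after injection, or None.

    Stage 1 finds the first frame after injection whose intensity exceeds
    ``baseline.mean + k * max(baseline.sd, sd_floor)`` for ``m`` consecutive
    frames within the analysis window.  Stage 2 walks backward from that
    crossing to the first frame still above
    ``baseline.mean + refine_margin * baseline.sd`` (no floor), which on a
    clean curve is the first frame after the true arrival.  Returns None
    (a flagged condition, not an error) when no crossing exists.
    """
    if k <= 0 or m < 1:
        raise InvalidInputError("need k > 0 and m >= 1")
    y = curve.intensities
    t = curve.times
    start = int(np.searchsorted(t, curve.injection_time + _EPS, side="left"))
    end = int(np.searchsorted(t, curve.injection_time + analysis_window + _EPS,
                              side="right"))
    if end - start < m:
        return None
    threshold = baseline.mean + k * max(baseline.sd, sd_floor)
    above = y[start:end] > threshold
    if m > 1:
        runs = sliding_window_view(above, m).all(axis=1)
    else:
        runs = above
    hits = np.flatnonzero(runs)
    if hits.size == 0:
        return None
    j = start + int(hits[0])
    margin = baseline.mean + refine_margin * baseline.sd
    # tolerance relative to the curve's dynamic range: invariant to constant
    # offsets and equivariant under intensity scaling
    tol = _EPS * max(1.0, float(np.ptp(y)))
    while j - 1 >= start and y[j - 1] > margin + tol:
        j -= 1
    return float(t[j])


# ---------------------------------------------------------------------- BSFI


def compute_bsfi(
    curve: TimeIntensityCurve,
    baseline: BaselineStats,
    analysis_window: float = defaults.ANALYSIS_WINDOW,
) -> tuple[float, float, float]:
    """Peak minus baseline within the first-passage window.

    The first passage is operationalized as the bounded window
    ``(injection, injection + analysis_window]``; the global maximum therein
    is the peak, ties resolving to the earliest frame.  A window extending
    past the recording is truncated.  Returns ``(bsfi, peak_time,
    peak_value)``.
    """
    t = curve.times
    sel = (t > curve.injection_time + _EPS) & (
        t <= curve.injection_time + analysis_window + _EPS
    )
    if not sel.any():
        raise UnusableCurveError("no frames inside the analysis window")
    y = curve.intensities[sel]
    tw = t[sel]
    i = int(np.argmax(y))  # argmax returns the earliest maximum
    peak_value = float(y[i])
    return peak_value - baseline.mean, float(tw[i]), peak_value


# ----------------------------------------------------------------------- SFI


def _window_slopes(t: np.ndarray, y: np.ndarray, width: int) -> np.ndarray:
    """Least-squares slope of every contiguous window of ``width`` samples."""
    tw = sliding_window_view(t, width)
    yw = sliding_window_view(y, width)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    return (tc * yc).sum(axis=1) / (tc * tc).sum(axis=1)


def compute_sfi(
    curve: TimeIntensityCurve,
    onset_time: float,
    peak_time: float,
    slope_window: int = defaults.SLOPE_WINDOW,
) -> tuple[float, bool]:
    """Maximal rising slope (a.u./s) between onset and peak.

    Scans every window of ``slope_window`` consecutive frames fully inside
    ``[onset_time, peak_time]`` and returns the largest least-squares slope,
    ties resolving to the earliest window.  A rising segment shorter than the
    window falls back to the full segment's regression slope and reports
    ``short_rise=True`` (NaN if the segment has fewer than 2 frames).
    """
    if slope_window < 2:
        raise InvalidInputError("slope_window must span >= 2 frames")
    t = curve.times
    i0 = int(np.searchsorted(t, onset_time - _EPS, side="left"))
    i1 = int(np.searchsorted(t, peak_time + _EPS, side="right")) - 1
    seg_t = t[i0 : i1 + 1]
    seg_y = curve.intensities[i0 : i1 + 1]
    if seg_t.size < 2:
        return float("nan"), True
    if seg_t.size < slope_window:
        return float(_window_slopes(seg_t, seg_y, seg_t.size)[0]), True
    slopes = _window_slopes(seg_t, seg_y, slope_window)
    return float(slopes[int(np.argmax(slopes))]), False


# ----------------------------------------------------------------- TTS ratio


def compute_tts_ratio(
    result: FIMetricsResult, reference: FIMetricsResult
) -> float:
    """``result.tts / reference.tts``; NaN (plus an ``undefined_ratio`` flag
    on ``result``) when either onset is missing or the reference TTS is 0."""
    if (
        "no_onset" in result.flags
        or "no_onset" in reference.flags
        or not np.isfinite(result.tts)
        or not np.isfinite(reference.tts)
        or reference.tts <= 0
    ):
        result.flags.add("undefined_ratio")
        return float("nan")
    return result.tts / reference.tts


# ------------------------------------------------------------- orchestration


def analyze_curve(
    curve: TimeIntensityCurve,
    reference: TimeIntensityCurve | FIMetricsResult | None = None,
    params: MetricParams | None = None,
) -> FIMetricsResult:
    """Full per-curve pipeline: baseline -> smooth -> onset -> BSFI -> SFI
    -> TTS ratio, with QC flags and parameter provenance."""
    params = params or MetricParams()
    flags: set[str] = set()

    baseline = baseline_statistics(curve, params.baseline_window)
    if baseline.short:
        flags.add("short_baseline")
    smoothed = smooth_curve(curve, params.smooth_half_width)

    onset = detect_onset(
        smoothed,
        baseline,
        k=params.onset_k,
        m=params.onset_m,
        sd_floor=params.sd_floor,
        refine_margin=params.onset_refine_margin,
        analysis_window=params.analysis_window,
    )
    bsfi, peak_time, peak_value = compute_bsfi(
        smoothed, baseline, params.analysis_window
    )

    if onset is None:
        flags.add("no_onset")
        sfi = tts = onset_out = float("nan")
    else:
        onset_out = onset
        tts = onset - curve.injection_time
        sfi, short_rise = compute_sfi(
            smoothed, onset, peak_time, params.slope_window
        )
        if short_rise:
            flags.add("short_rise")

    if curve.ceiling is not None:
        sel = (curve.times > curve.injection_time) & (
            curve.times <= curve.injection_time + params.analysis_window
        )
        frac = float(np.mean(curve.intensities[sel] >= curve.ceiling - _EPS))
        if frac > params.saturation_flag_fraction:
            flags.add("saturated")

    result = FIMetricsResult(
        roi_name=curve.roi_name,
        state_label=curve.state_label,
        bsfi=float(bsfi),
        sfi=float(sfi),
        tts=float(tts),
        onset_time=float(onset_out),
        peak_time=float(peak_time),
        peak_value=float(peak_value),
        baseline_mean=baseline.mean,
        baseline_sd=baseline.sd,
        flags=flags,
        params=asdict(params),
    )
    if reference is not None:
        if isinstance(reference, TimeIntensityCurve):
            reference = analyze_curve(reference, params=params)
        result.tts_ratio = compute_tts_ratio(result, reference)
    return result
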