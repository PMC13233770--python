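"""Morphometric channels, trend extraction and per-frame shape descriptors.

Six time series are computed per animal from the landmark contour:
whole-body polygon area, trunk polygon area, oral- and atrial-siphon
opening widths (dorsal-rim to ventral-rim Euclidean distance), and the two
four-point siphon areas.  Pixel measurements are converted to micrometers
via the recording's mm-per-pixel scale.  Channels are median-normalized,
outlier-filtered and gap-interpolated, then passed through a classical
additive seasonal decomposition (50-frame period) whose z-scored trend is
the substrate for contraction-event detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import seasonal_decompose

from .bodyplan import BodyPlan
from .io import LandmarkSeries

__all__ = [
    "MetricSeries", "TrendSeries", "ShapeDescriptors",
    "polygon_area", "siphon_width", "compute_metrics",
    "normalize_and_clean", "decompose_trend", "shape_descriptors",
    "METRIC_CHANNELS", "INFORMATIVE_CHANNELS",
]

METRIC_CHANNELS = ("whole_area", "trunk_area", "os_width", "as_width",
                   "os_area", "as_area")
#: the three channels that define the postural-engagement states
INFORMATIVE_CHANNELS = ("trunk_area", "os_width", "as_width")


@dataclass
class MetricSeries:
    """The six morphometric channels of one recording (µm / µm² or unitless
    after median normalization)."""

    channels: dict
    fps: float
    units: str = "um"
    animal_id: str = ""
    condition: str = ""
    stimulus_onset: int | None = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.channels.values())))

    def finite_mask(self, channel: str) -> np.ndarray:
        return np.isfinite(self.channels[channel])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.channels)
        df.insert(0, "frame", np.arange(self.n_frames))
        df.insert(1, "time_s", df["frame"] / self.fps)
        return df


@dataclass
class TrendSeries:
    """Z-scored decomposition trends of the six channels."""

    channels: dict
    fps: float
    period: int = 50
    valid_bounds: dict = field(default_factory=dict)
    animal_id: str = ""
    condition: str = ""
    stimulus_onset: int | None = None

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass
class ShapeDescriptors:
    aspect_ratio: float
    solidity: float
    body_angle: float   # degrees from image horizontal, folded to [0, 90]
    dv_ratio: float


# --------------------------------------------------------------------------
# per-frame primitives

def polygon_area(points: np.ndarray) -> float:
    """Shoelace area (absolute value) of an ordered polygon.

    Returns NaN if any vertex is NaN.  Self-intersection is not checked
    here; invalid frames are rejected upstream by the contour validator.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional vertices")
    if not np.all(np.isfinite(pts)):
        return float("nan")
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def siphon_width(coords: np.ndarray, pair: tuple[int, int]) -> float:
    """Euclidean distance between the dorsal and ventral rim points."""
    a, b = coords[pair[0]], coords[pair[1]]
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


# --------------------------------------------------------------------------
# channel extraction

def compute_metrics(series: LandmarkSeries, plan: BodyPlan) -> MetricSeries:
    """Extract the six channels per frame, converted to micrometers.

    Frames with any NaN vertex in a region report NaN for that region's
    channels.  Expects a masked (p-cutoff applied) and downsampled series.
    """
    if series.n_landmarks != plan.n_landmarks:
        raise ValueError("landmark count does not match the body plan")
    um_per_px = series.pixel_scale * 1000.0
    T = series.n_frames
    out = {name: np.full(T, np.nan) for name in METRIC_CHANNELS}
    body = list(plan.body_polygon)
    trunk = list(plan.trunk_polygon)
    for t in range(T):
        c = series.coords[t]
        out["whole_area"][t] = polygon_area(c[body]) * um_per_px ** 2
        out["trunk_area"][t] = polygon_area(c[trunk]) * um_per_px ** 2
        out["os_area"][t] = polygon_area(c[list(plan.os_quad)]) * um_per_px ** 2
        out["as_area"][t] = polygon_area(c[list(plan.as_quad)]) * um_per_px ** 2
        if np.all(np.isfinite(c[list(plan.os_width_pair)])):
            out["os_width"][t] = siphon_width(c, plan.os_width_pair) * um_per_px
        if np.all(np.isfinite(c[list(plan.as_width_pair)])):
            out["as_width"][t] = siphon_width(c, plan.as_width_pair) * um_per_px
    return MetricSeries(channels=out, fps=series.fps, units="um",
                        animal_id=series.animal_id, condition=series.condition,
                        stimulus_onset=series.stimulus_onset)


# --------------------------------------------------------------------------
# cleaning

def _interpolate_short_gaps(x: np.ndarray, max_gap: int) -> np.ndarray:
    """Linear interpolation of interior NaN runs of length <= max_gap."""
    x = x.copy()
    finite = np.isfinite(x)
    if finite.sum() < 2:
        return x
    idx = np.arange(len(x))
    start = None
    for i in range(len(x) + 1):
        if i < len(x) and not finite[i]:
            if start is None:
                start = i
        elif start is not None:
            run = i - start
            if run <= max_gap and start > 0 and i < len(x):
                x[start:i] = np.interp(idx[start:i], [start - 1, i],
                                       [x[start - 1], x[i]])
            start = None
    return x


def normalize_and_clean(metrics: MetricSeries, max_gap: int = 20,
                        mad_k: float = 5.0, outlier_floor: float = 1.0) -> MetricSeries:
    """Median-normalize, filter outliers, interpolate short gaps.

    Each channel is divided by its own median (per animal); values
    deviating from the normalized median by more than
    ``max(mad_k · MAD, outlier_floor)`` are set NaN; NaN runs of
    <= ``max_gap`` frames are linearly interpolated, longer runs are left
    missing.  Idempotent on clean data.

    The floor (in median-normalized units, default 1.0 = 100% of the
    median) keeps the robust rule from clipping genuine contraction
    excursions: in quiescence-dominated recordings the MAD is set by
    tracking noise, while real contractions can shrink a channel by more
    than half its median — a downward physiological excursion can never
    exceed a deviation of 1.0, whereas tracking glitches (landmark swaps,
    reflections) overshoot by several multiples of the median.
    """
    out = {}
    for name, values in metrics.channels.items():
        x = np.asarray(values, dtype=float)
        med = np.nanmedian(x)
        if not np.isfinite(med) or med == 0:
            # degenerate channel: leave unnormalized, flagged by caller via QC
            out[name] = x.copy()
            continue
        x = x / med
        dev = np.abs(x - np.nanmedian(x))
        mad = np.nanmedian(dev)
        threshold = max(mad_k * mad, outlier_floor)
        x = np.where(dev > threshold, np.nan, x)
        out[name] = _interpolate_short_gaps(x, max_gap)
    return MetricSeries(channels=out, fps=metrics.fps, units="normalized",
                        animal_id=metrics.animal_id, condition=metrics.condition,
                        stimulus_onset=metrics.stimulus_onset)


# --------------------------------------------------------------------------
# trend decomposition

def _zscore(x: np.ndarray) -> np.ndarray:
    mu = np.nanmean(x)
    sd = np.nanstd(x)
    if not np.isfinite(sd) or sd == 0:
        return x - mu
    return (x - mu) / sd


def decompose_trend(metrics: MetricSeries, period: int = 50,
                    start_fit: int = 25, max_trend_gap: int = 200) -> TrendSeries:
    """Classical additive decomposition; z-scored trend per channel.

    The trend is the centered moving average of window ``period``; the
    leading (and trailing) undefined half-window is reconstructed by a
    linear fit over the first (last) ``start_fit`` valid trend frames, and
    interior trend gaps of <= ``max_trend_gap`` frames are interpolated.
    ``valid_bounds`` marks the first and last defined trend frame per
    channel so boundary artifacts can be excluded downstream.
    """
    T = metrics.n_frames
    if T < 2 * period:
        raise ValueError(f"series of {T} frames shorter than 2 x period ({period})")
    trends: dict = {}
    bounds: dict = {}
    idx = np.arange(T)
    for name, values in metrics.channels.items():
        raw = np.asarray(values, dtype=float)
        # the classical decomposition needs a complete series: fill missing
        # frames linearly for the moving average, then re-mask long gaps
        filled = pd.Series(raw).interpolate(limit_direction="both").to_numpy()
        if np.any(~np.isfinite(filled)):  # all-NaN channel
            trends[name] = raw.copy()
            bounds[name] = (0, T - 1)
            continue
        trend = seasonal_decompose(pd.Series(filled), model="additive",
                                   period=period,
                                   extrapolate_trend=0).trend.to_numpy()
        finite_raw = np.isfinite(raw)
        start = None
        for i in range(T + 1):
            if i < T and not finite_raw[i]:
                start = i if start is None else start
            elif start is not None:
                if i - start > max_trend_gap:
                    trend[start:i] = np.nan
                start = None
        trend = _interpolate_short_gaps(trend, max_trend_gap)
        finite = np.isfinite(trend)
        if finite.sum() >= 2:
            first, last = int(np.argmax(finite)), int(T - 1 - np.argmax(finite[::-1]))
            for lo, hi, sl in ((first, first + start_fit, slice(0, first)),
                               (max(first, last - start_fit + 1), last + 1,
                                slice(last + 1, T))):
                seg = idx[lo:hi][np.isfinite(trend[lo:hi])]
                if len(seg) >= 2 and sl.stop > sl.start:
                    coef = np.polyfit(seg, trend[seg], 1)
                    trend[sl] = np.polyval(coef, idx[sl])
            bounds[name] = (first, last)
        else:
            bounds[name] = (0, T - 1)
        trends[name] = _zscore(trend)
    return TrendSeries(channels=trends, fps=metrics.fps, period=period,
                       valid_bounds=bounds, animal_id=metrics.animal_id,
                       condition=metrics.condition,
                       stimulus_onset=metrics.stimulus_onset)


# --------------------------------------------------------------------------
# shape descriptors

def _convex_hull_area(pts: np.ndarray) -> float:
    from scipy.spatial import ConvexHull
    return float(ConvexHull(pts).volume)  # 2-d: volume == area


def _fit_ellipse_axes(pts: np.ndarray) -> tuple[float, float]:
    """Half-axis lengths of the least-squares (second-moment) ellipse."""
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    evals = np.clip(evals, 0, None)
    return 2.0 * np.sqrt(evals[0]), 2.0 * np.sqrt(evals[1])


def shape_descriptors(coords: np.ndarray, plan: BodyPlan) -> ShapeDescriptors:
    """Aspect ratio, solidity, body angle and D/V ratio of one frame.

    aspect_ratio: long/short axis of the moment-fitted ellipse (>= 1);
    solidity: polygon area / convex-hull area (in (0, 1]);
    body_angle: orientation of the first principal axis of the vertex
    cloud versus the image horizontal, folded to [0°, 90°] (the outline
    has no canonical head direction in 2-D);
    dv_ratio: dorsal-side over ventral-side contour arc length (the two
    halves of the outline split at the topmost and bottommost vertices).
    """
    pts = np.asarray(coords, dtype=float)[list(plan.body_polygon)]
    if not np.all(np.isfinite(pts)):
        return ShapeDescriptors(np.nan, np.nan, np.nan, np.nan)
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[-1], 1e-300):  # collinear outline
        return ShapeDescriptors(np.nan, np.nan, np.nan, np.nan)
    major, minor = _fit_ellipse_axes(pts)
    aspect = major / minor if minor > 0 else np.nan
    area = polygon_area(pts)
    hull = _convex_hull_area(pts)
    solidity = area / hull if hull > 0 else np.nan
    vx, vy = evecs[:, -1]  # principal axis
    angle = np.degrees(np.arctan2(abs(vy), abs(vx)))  # fold to [0, 90]
    # arc lengths of the two contour halves between extreme-y vertices
    y = pts[:, 1]
    i_top, i_bot = int(np.argmin(y)), int(np.argmax(y))
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    lo, hi = sorted((i_top, i_bot))
    side_a = float(seg[lo:hi].sum())
    side_b = float(seg.sum() - side_a)
    dv = side_a / side_b if side_b > 0 else np.nan
    return ShapeDescriptors(float(aspect), float(solidity), float(angle), float(dv))


def normalize_descriptors(per_frame: pd.DataFrame) -> pd.DataFrame:
    """Divide each descriptor by the animal's median across all frames
    (the per-animal normalization used before state comparisons)."""
    med = per_frame.median(numeric_only=True)
    return per_frame / med
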