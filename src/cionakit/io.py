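"""Reading, writing and quality control of DeepLabCut-style landmark CSVs.

The on-disk dialect mirrors filtered single-animal DeepLabCut output: three
header rows (scorer / bodyparts / coords) over ``x, y, likelihood`` triplets
per body part, one data row per frame, empty cells for missing values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bodyplan import BodyPlan

__all__ = [
    "LandmarkSeries",
    "read_dlc_csv",
    "write_dlc_csv",
    "mask_low_confidence",
    "downsample",
    "qc_coverage",
    "read_manifest",
    "write_manifest",
]


@dataclass
class LandmarkSeries:
    """Per-recording keypoint trajectories.

    ``coords`` is ``(T, 18, 2)`` in pixels, image convention (x right,
    y down, origin top-left); ``likelihood`` is ``(T, 18)`` in [0, 1].
    """

    coords: np.ndarray
    likelihood: np.ndarray
    fps: float = 20.0
    pixel_scale: float = 0.254  # mm per pixel
    animal_id: str = "animal0"
    condition: str = "control"
    stimulus_onset: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must be (T, n_landmarks, 2)")
        if self.likelihood.shape != self.coords.shape[:2]:
            raise ValueError("likelihood must be (T, n_landmarks)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        finite = np.isfinite(self.likelihood)
        if np.any((self.likelihood[finite] < 0) | (self.likelihood[finite] > 1)):
            raise ValueError("likelihood must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame / fps, 0-based)."""
        return np.arange(self.n_frames) / self.fps


def read_dlc_csv(path: str | Path, plan: BodyPlan) -> LandmarkSeries:
    """Parse a DeepLabCut-style CSV into a :class:`LandmarkSeries`.

    Body-part columns may appear in any order; they are reordered to match
    ``plan.landmark_names``.  Empty cells become NaN coordinates with
    likelihood 0.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise ValueError(f"{path}: not a DLC CSV (fewer than 3 header rows)")
    bodyparts_row, coords_row = rows[1], rows[2]
    if rows[0][0] != "scorer" or bodyparts_row[0] != "bodyparts" or coords_row[0] != "coords":
        raise ValueError(f"{path}: unexpected DLC header rows")

    # column index of the x column for each body part
    part_col: dict[str, int] = {}
    for j in range(1, len(bodyparts_row)):
        if coords_row[j] == "x":
            part_col.setdefault(bodyparts_row[j], j)
    missing = [p for p in plan.landmark_names if p not in part_col]
    if missing:
        raise ValueError(f"{path}: missing body part column(s): {', '.join(missing)}")

    data = rows[3:]
    T = len(data)
    coords = np.full((T, plan.n_landmarks, 2), np.nan)
    likelihood = np.zeros((T, plan.n_landmarks))
    for t, row in enumerate(data):
        for k, name in enumerate(plan.landmark_names):
            j = part_col[name]
            cx, cy, cl = row[j], row[j + 1], row[j + 2]
            try:
                if cx != "" and cy != "":
                    coords[t, k, 0] = float(cx)
                    coords[t, k, 1] = float(cy)
                likelihood[t, k] = float(cl) if cl != "" else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell in data row {t}") from exc
    return LandmarkSeries(coords=coords, likelihood=likelihood)


def write_dlc_csv(series: LandmarkSeries, path: str | Path,
                  plan: BodyPlan, scorer: str = "cionakit") -> Path:
    """Write a series in the DLC CSV dialect (round-trips with the reader)."""
    path = Path(path)
    names = plan.landmark_names
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["scorer"] + [scorer] * (3 * len(names)))
        w.writerow(["bodyparts"] + [n for n in names for _ in range(3)])
        w.writerow(["coords"] + ["x", "y", "likelihood"] * len(names))
        for t in range(series.n_frames):
            row: list[str] = [str(t)]
            for k in range(len(names)):
                x, y = series.coords[t, k]
                lk = series.likelihood[t, k]
                if np.isfinite(x) and np.isfinite(y):
                    row += [repr(float(x)), repr(float(y)), repr(float(lk))]
                else:
                    row += ["", "", "0.0"]
            w.writerow(row)
    return path


def mask_low_confidence(series: LandmarkSeries, p_cutoff: float = 0.6) -> LandmarkSeries:
    """NaN-out coordinates whose likelihood falls below ``p_cutoff``.

    Idempotent; the default cutoff is the standard DLC filtering value 0.6.
    """
    if not 0 <= p_cutoff <= 1:
        raise ValueError("p_cutoff must lie in [0, 1]")
    coords = series.coords.copy()
    coords[series.likelihood < p_cutoff] = np.nan
    return replace(series, coords=coords, likelihood=series.likelihood.copy())


def downsample(series: LandmarkSeries, factor: int = 5) -> LandmarkSeries:
    """Temporal decimation: keep every ``factor``-th frame starting at frame 0.

    20 Hz recordings downsampled 1:5 yield the 4 Hz analysis rate.  The
    stimulus-onset frame is rescaled by integer division.
    """
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError("factor must be a positive integer")
    onset = series.stimulus_onset
    return replace(
        series,
        coords=series.coords[::factor].copy(),
        likelihood=series.likelihood[::factor].copy(),
        fps=series.fps / factor,
        stimulus_onset=None if onset is None else int(onset) // factor,
    )


def qc_coverage(metrics: "MetricSeries", min_fraction: float = 0.20):
    """Retention check: every metric channel needs ≥ ``min_fraction`` finite frames.

    Returns ``(retain, per_channel_coverage)``.  The threshold is inclusive.
    """
    from .morphometry import MetricSeries  # local import avoids a cycle

    if not isinstance(metrics, MetricSeries):
        raise TypeError("qc_coverage expects a MetricSeries")
    if metrics.n_frames == 0:
        raise ValueError("empty metric series")
    coverage = {
        name: float(np.mean(np.isfinite(values)))
        for name, values in metrics.channels.items()
    }
    retain = all(c >= min_fraction for c in coverage.values())
    return retain, coverage


MANIFEST_COLUMNS = [
    "animal_id", "path", "condition", "stimulus_onset_frame",
    "pixel_scale_mm_per_px", "fps",
]


def write_manifest(records: list[dict], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(records, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
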