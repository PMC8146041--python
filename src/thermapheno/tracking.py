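"""Per-vial video tracking.

Converts frame sequences of backlit vial racks into per-individual track
series: centroid detection by reference-image subtraction, body-centre
distance steps in centimetres, a motion-energy activity signal, and
upper/lower zone classification against each vial's middle line.

One fly per vial by design; no identity maintenance is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .core import ZONE_LOWER, ZONE_UNDETECTED, ZONE_UPPER, CalibrationScale

logger = logging.getLogger(__name__)

TRACK_COLUMNS = [
    "individual_id",
    "time_s",
    "x_mm",
    "y_mm",
    "distance_cm",
    "activity",
    "zone",
]


@dataclass(frozen=True)
class VialROI:
    """Rectangular region of interest for a single vial.

    ``bbox_px`` is (top, left, bottom, right), half-open on the bottom/right
    edge. ``middle_line_y_px`` marks the vial's centre line; a fly strictly
    above it (smaller image row) is in the upper zone.
    """

    vial_id: str
    bbox_px: tuple[int, int, int, int]
    middle_line_y_px: float

    def __post_init__(self) -> None:
        top, left, bottom, right = self.bbox_px
        if not (top < bottom and left < right):
            raise ValueError(f"degenerate bbox for vial {self.vial_id!r}")
        if not (top < self.middle_line_y_px < bottom):
            raise ValueError(
                f"middle line must lie strictly inside the bbox of vial "
                f"{self.vial_id!r}"
            )

    def contains(self, row: float, col: float) -> bool:
        top, left, bottom, right = self.bbox_px
        return top <= row < bottom and left <= col < right


def _check_disjoint(rois: list[VialROI]) -> None:
    for i, a in enumerate(rois):
        for b in rois[i + 1 :]:
            t1, l1, b1, r1 = a.bbox_px
            t2, l2, b2, r2 = b.bbox_px
            if t1 < b2 and t2 < b1 and l1 < r2 and l2 < r1:
                raise ValueError(f"overlapping ROIs: {a.vial_id!r}, {b.vial_id!r}")


@dataclass
class TrackSeries:
    """Time-ordered track of one individual.

    Columnar storage: all arrays share one length. ``x_mm``/``y_mm`` are NaN
    where the fly was undetected; ``zone`` is ``undetected`` exactly there.
    The distance step is zero at the first detected frame and across
    detection gaps (gaps are never interpolated — interpolation would
    fabricate movement near coma, exactly where traits are read).
    """

    individual_id: str
    assay_id: str
    treatment_label: str
    frame_rate_hz: float
    time_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    distance_cm: np.ndarray
    activity: np.ndarray
    zone: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("x_mm", "y_mm", "distance_cm", "activity", "zone"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch for {name}")
        if n > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > 1e-6 * dt.mean():
                raise ValueError("non-uniform frame spacing")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "time_s": self.time_s,
                "x_mm": self.x_mm,
                "y_mm": self.y_mm,
                "distance_cm": self.distance_cm,
                "activity": self.activity,
                "zone": self.zone,
            }
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        frame_rate_hz: float,
        assay_id: str = "",
        treatment_label: str = "",
    ) -> "TrackSeries":
        ind = df["individual_id"].iloc[0]
        return cls(
            individual_id=str(ind),
            assay_id=assay_id,
            treatment_label=treatment_label,
            frame_rate_hz=frame_rate_hz,
            time_s=df["time_s"].to_numpy(float),
            x_mm=df["x_mm"].to_numpy(float),
            y_mm=df["y_mm"].to_numpy(float),
            distance_cm=df["distance_cm"].to_numpy(float),
            activity=df["activity"].to_numpy(float),
            zone=df["zone"].to_numpy(str),
        )


def tracks_to_dataframe(series_list: list[TrackSeries]) -> pd.DataFrame:
    """Merge tracks into one long table ordered by (individual, time)."""
    frames = [s.to_dataframe() for s in series_list]
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["individual_id", "time_s"], kind="stable").reset_index(
        drop=True
    )


def tracks_from_dataframe(
    df: pd.DataFrame, frame_rate_hz: float, assay_id: str = ""
) -> list[TrackSeries]:
    treatments = (
        df.groupby("individual_id")["treatment_label"].first()
        if "treatment_label" in df
        else None
    )
    out = []
    for ind, grp in df.groupby("individual_id", sort=True):
        label = str(treatments[ind]) if treatments is not None else ""
        out.append(
            TrackSeries.from_dataframe(
                grp.sort_values("time_s"),
                frame_rate_hz,
                assay_id=assay_id,
                treatment_label=label,
            )
        )
    return out


def detect_fly(
    frame: np.ndarray,
    reference: np.ndarray,
    roi: VialROI,
    threshold: float = 20.0,
    min_size_px: int = 4,
) -> tuple[float, float] | None:
    """Centroid (row, col) of the largest foreground blob inside the ROI.

    Returns None when no connected component of the thresholded
    frame-reference difference reaches ``min_size_px`` inside the ROI.
    """
    if frame.shape != reference.shape:
        raise ValueError("frame and reference dimensions differ")
    top, left, bottom, right = roi.bbox_px
    if top < 0 or left < 0 or bottom > frame.shape[0] or right > frame.shape[1]:
        raise ValueError(f"ROI {roi.vial_id!r} outside frame bounds")
    sub = frame[top:bottom, left:right].astype(np.float64)
    ref = reference[top:bottom, left:right].astype(np.float64)
    mask = np.abs(sub - ref) > threshold
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return None
    regions = measure.regionprops(labels)
    best = max(regions, key=lambda r: r.area)
    if best.area < min_size_px:
        return None
    cy, cx = best.centroid
    return (cy + top, cx + left)


def distance_step(
    prev_centroid_mm: tuple[float, float] | None,
    curr_centroid_mm: tuple[float, float] | None,
) -> float:
    """Body-centre Euclidean step in centimetres (inputs in mm).

    Either endpoint absent contributes a zero step.
    """
    if prev_centroid_mm is None or curr_centroid_mm is None:
        return 0.0
    dx = curr_centroid_mm[0] - prev_centroid_mm[0]
    dy = curr_centroid_mm[1] - prev_centroid_mm[1]
    return float(np.hypot(dx, dy)) / 10.0


def activity_signal(
    frame: np.ndarray,
    prev_frame: np.ndarray,
    roi: VialROI,
    pixel_threshold: float = 10.0,
) -> float:
    """Motion energy: fraction of ROI pixels changed beyond a noise floor.

    A monotone proxy for a tracking package's activity channel; only its
    zero/non-zero semantics feed trait extraction.
    """
    top, left, bottom, right = roi.bbox_px
    a = frame[top:bottom, left:right].astype(np.float64)
    b = prev_frame[top:bottom, left:right].astype(np.float64)
    changed = np.abs(a - b) > pixel_threshold
    return float(changed.mean())


def classify_zone(centroid_px: tuple[float, float], roi: VialROI) -> str:
    """Upper iff strictly above the middle line; on the line counts as lower."""
    row = centroid_px[0]
    return ZONE_UPPER if row < roi.middle_line_y_px else ZONE_LOWER


def track_assay(
    frames,
    rois: list[VialROI],
    cal: CalibrationScale,
    reference: np.ndarray,
    frame_rate_hz: float,
    threshold: float = 20.0,
    pixel_threshold: float = 10.0,
    min_size_px: int = 4,
    assay_id: str = "",
    treatment_labels: dict[str, str] | None = None,
) -> list[TrackSeries]:
    """Track every vial through a frame sequence.

    Returns one TrackSeries per ROI (empty vials yield all-undetected series,
    retained and logged). Deterministic for fixed input.
    """
    _check_disjoint(rois)
    frames = list(frames)
    n = len(frames)
    ppm = cal.pixels_per_mm
    per_roi: dict[str, dict[str, np.ndarray]] = {
        r.vial_id: {
            "x": np.full(n, np.nan),
            "y": np.full(n, np.nan),
            "dist": np.zeros(n),
            "act": np.zeros(n),
            "zone": np.full(n, ZONE_UNDETECTED, dtype=object),
        }
        for r in rois
    }
    prev_centroids: dict[str, tuple[float, float] | None] = {
        r.vial_id: None for r in rois
    }
    prev_frame = None
    for i, frame in enumerate(frames):
        if frame.shape != reference.shape:
            raise ValueError("inconsistent frame dimensions")
        for roi in rois:
            buf = per_roi[roi.vial_id]
            c = detect_fly(frame, reference, roi, threshold, min_size_px)
            if c is not None:
                x_mm, y_mm = c[1] / ppm, c[0] / ppm
                buf["x"][i], buf["y"][i] = x_mm, y_mm
                buf["zone"][i] = classify_zone(c, roi)
                prev_mm = prev_centroids[roi.vial_id]
                buf["dist"][i] = distance_step(prev_mm, (x_mm, y_mm))
                prev_centroids[roi.vial_id] = (x_mm, y_mm)
            else:
                prev_centroids[roi.vial_id] = None
            if i > 0:
                buf["act"][i] = activity_signal(frame, prev_frame, roi, pixel_threshold)
        prev_frame = frame
    out = []
    time_s = np.arange(n, dtype=float) / frame_rate_hz
    for roi in rois:
        buf = per_roi[roi.vial_id]
        n_gaps = int(np.isnan(buf["x"]).sum())
        if n_gaps == n:
            logger.warning("vial %s: no detections in %d frames", roi.vial_id, n)
        elif n_gaps:
            logger.info("vial %s: %d undetected frames", roi.vial_id, n_gaps)
        label = (treatment_labels or {}).get(roi.vial_id, "")
        out.append(
            TrackSeries(
                individual_id=roi.vial_id,
                assay_id=assay_id,
                treatment_label=label,
                frame_rate_hz=frame_rate_hz,
                time_s=time_s,
                x_mm=buf["x"],
                y_mm=buf["y"],
                distance_cm=buf["dist"],
                activity=buf["act"],
                zone=np.asarray(buf["zone"], dtype=object),
            )
        )
    return out
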