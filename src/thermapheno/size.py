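"""Calibrated larval surface area from backlit well-plate frames.

A reference image of the empty plate is subtracted from each acquisition
frame; pixels that differ by more than a threshold form the foreground,
connected components are assigned to wells by centroid membership, and the
largest blob per well is the larva. Areas are pixel counts converted through
the squared calibration scale. One acquisition yields a per-frame mean; three
technical replicates per individual give a mean and a CV%.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from .core import CalibrationScale

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Well:
    well_id: str
    center_px: tuple[float, float]  # (row, col)
    radius_px: float

    def contains(self, row: float, col: float) -> bool:
        dr = row - self.center_px[0]
        dc = col - self.center_px[1]
        return dr * dr + dc * dc <= self.radius_px**2


@dataclass(frozen=True)
class PlateLayout:
    """Disjoint circular wells on one plate (default protocol: 30 wells)."""

    wells: tuple[Well, ...]
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate well ids")
        for i, a in enumerate(self.wells):
            for b in self.wells[i + 1 :]:
                d = np.hypot(
                    a.center_px[0] - b.center_px[0], a.center_px[1] - b.center_px[1]
                )
                if d < a.radius_px + b.radius_px:
                    raise ValueError(
                        f"overlapping wells {a.well_id!r} and {b.well_id!r}"
                    )

    def well_of(self, row: float, col: float) -> Well | None:
        for w in self.wells:
            if w.contains(row, col):
                return w
        return None

    @classmethod
    def grid(
        cls,
        n_rows: int = 5,
        n_cols: int = 6,
        well_radius_px: float = 45.0,
        pitch_px: float = 100.0,
        origin_px: tuple[float, float] = (60.0, 60.0),
    ) -> "PlateLayout":
        """Regular grid layout; the 5×6 default mirrors a 30-well plate."""
        wells = []
        for r in range(n_rows):
            for c in range(n_cols):
                wells.append(
                    Well(
                        well_id=f"W{r * n_cols + c + 1:02d}",
                        center_px=(origin_px[0] + r * pitch_px, origin_px[1] + c * pitch_px),
                        radius_px=well_radius_px,
                    )
                )
        return cls(wells=tuple(wells), n_rows=n_rows, n_cols=n_cols)

    def image_shape(self, margin_px: float = 60.0) -> tuple[int, int]:
        rows = max(w.center_px[0] + w.radius_px for w in self.wells) + margin_px
        cols = max(w.center_px[1] + w.radius_px for w in self.wells) + margin_px
        return (int(np.ceil(rows)), int(np.ceil(cols)))

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "wells": [
                {
                    "well_id": w.well_id,
                    "center_px": list(w.center_px),
                    "radius_px": w.radius_px,
                }
                for w in self.wells
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        wells = tuple(
            Well(w["well_id"], tuple(w["center_px"]), w["radius_px"])
            for w in d["wells"]
        )
        return cls(wells=wells, n_rows=d["n_rows"], n_cols=d["n_cols"])

    @classmethod
    def from_json(cls, path) -> "PlateLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Blob:
    """A connected foreground component."""

    area_px: int
    centroid_px: tuple[float, float]


@dataclass(frozen=True)
class SizeMeasurement:
    """Per-individual area with technical replicates.

    CV% uses the sample standard deviation (n−1), the common convention for
    triplicate technical replicates.
    """

    individual_id: str
    replicate_areas_mm2: tuple[float, ...]
    mean_area_mm2: float
    cv_percent: float


def segment_foreground(
    frame: np.ndarray, reference: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Boolean mask of pixels differing from the reference beyond a threshold.

    ``threshold=None`` picks an Otsu threshold on the absolute difference
    image (deterministic automatic default; falls back to an empty mask when
    the difference image is constant, i.e. frame == reference).
    """
    if frame.shape != reference.shape:
        raise ValueError("frame and reference dimensions differ")
    diff = np.abs(frame.astype(np.float64) - reference.astype(np.float64))
    if threshold is None:
        if np.ptp(diff) == 0:
            return np.zeros(frame.shape, dtype=bool)
        threshold = float(threshold_otsu(diff))
    return diff > threshold


def assign_blobs_to_wells(
    mask: np.ndarray, layout: PlateLayout
) -> dict[str, Blob | None]:
    """Largest blob per well, by centroid membership; strays are discarded.

    Absence is a valid state: wells with no blob map to None. Components
    whose centroid lies in no well disk are discarded and logged.
    8-connectivity throughout.
    """
    labels = measure.label(mask, connectivity=2)
    best: dict[str, Blob | None] = {w.well_id: None for w in layout.wells}
    n_stray = 0
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        well = layout.well_of(cy, cx)
        if well is None:
            n_stray += 1
            continue
        cur = best[well.well_id]
        if cur is None or region.area > cur.area_px:
            best[well.well_id] = Blob(int(region.area), (float(cy), float(cx)))
    if n_stray:
        logger.info("discarded %d blob(s) outside all wells", n_stray)
    return best


def area_of(blob: Blob, cal: CalibrationScale) -> float:
    """Blob area in mm²: pixel count over the squared calibration scale."""
    if blob is None or blob.area_px == 0:
        raise ValueError("empty blob has no area")
    return cal.area_px2_to_mm2(blob.area_px)


def acquire_mean_area(
    frames,
    layout: PlateLayout,
    cal: CalibrationScale,
    reference: np.ndarray,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-well mean area over an acquisition window of frames.

    Frames where a larva goes undetected are dropped from that larva's mean
    (treating them as zero would bias the mean) and counted. A well with no
    detection in any frame is flagged missing (NaN mean).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    per_well: dict[str, list[float]] = {w.well_id: [] for w in layout.wells}
    for frame in frames:
        mask = segment_foreground(frame, reference, threshold)
        blobs = assign_blobs_to_wells(mask, layout)
        for wid, blob in blobs.items():
            if blob is not None:
                per_well[wid].append(area_of(blob, cal))
    rows = []
    for w in layout.wells:
        areas = per_well[w.well_id]
        rows.append(
            {
                "well_id": w.well_id,
                "mean_area_mm2": float(np.mean(areas)) if areas else np.nan,
                "n_frames_used": len(areas),
                "n_frames_total": len(frames),
                "missing": not areas,
            }
        )
    return pd.DataFrame(rows)


def replicate_stats(
    replicate_means: list[float], individual_id: str = ""
) -> SizeMeasurement:
    """Mean and CV% over technical replicates (sample sd, n−1)."""
    reps = [float(x) for x in replicate_means]
    if len(reps) < 1:
        raise ValueError("need at least one replicate")
    mean = float(np.mean(reps))
    if mean == 0:
        raise ValueError("zero mean area: CV undefined")
    if len(reps) >= 2:
        cv = 100.0 * float(np.std(reps, ddof=1)) / mean
    else:
        cv = 0.0
    return SizeMeasurement(
        individual_id=individual_id,
        replicate_areas_mm2=tuple(reps),
        mean_area_mm2=mean,
        cv_percent=cv,
    )


def measure_replicates(
    acquisitions: list[pd.DataFrame], id_prefix: str = ""
) -> pd.DataFrame:
    """Combine per-acquisition mean-area tables into one replicate table.

    ``acquisitions`` are outputs of :func:`acquire_mean_area` for the same
    plate (one per technical replicate).
    """
    if len(acquisitions) < 1:
        raise ValueError("need at least one acquisition")
    rows = []
    for w in acquisitions[0]["well_id"]:
        reps = []
        for acq in acquisitions:
            v = acq.loc[acq["well_id"] == w, "mean_area_mm2"].iloc[0]
            if np.isfinite(v):
                reps.append(float(v))
        ind = f"{id_prefix}{w}"
        if not reps:
            rows.append(
                {
                    "individual_id": ind,
                    "replicate_areas_mm2": "",
                    "mean_area_mm2": np.nan,
                    "cv_percent": np.nan,
                    "n_replicates": 0,
                }
            )
            continue
        m = replicate_stats(reps, individual_id=ind)
        rows.append(
            {
                "individual_id": ind,
                "replicate_areas_mm2": ";".join(f"{a:.6g}" for a in reps),
                "mean_area_mm2": m.mean_area_mm2,
                "cv_percent": m.cv_percent,
                "n_replicates": len(reps),
            }
        )
    return pd.DataFrame(rows)
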