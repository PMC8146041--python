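"""Post-tracking signal transforms.

Raw per-frame distance and activity are summed into 15-s intervals; the
assay-level background noise (lighting changes, bubbles, camera disturbance)
is quantified as the maximum binned distance and activity inside a declared
quiescent window of a static high-temperature recording, where all real
activity has ceased; that maximum is subtracted from every bin of every
assay, with sub-zero values corrected to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ZONE_UPPER
from .tracking import TrackSeries

DEFAULT_BIN_WIDTH_S = 15.0


@dataclass
class BinnedSeries:
    """Per-individual binned distance/activity and upper-zone detection.

    Bins are half-open ``[k·w, (k+1)·w)`` anchored at the assay start; a
    final partial bin is kept and flagged. Before filtering, bin sums
    conserve the raw totals exactly (up to float summation order).
    """

    individual_id: str
    assay_id: str
    treatment_label: str
    bin_width_s: float
    bin_start_s: np.ndarray
    distance_cm: np.ndarray
    activity: np.ndarray
    upper_zone_detected: np.ndarray
    partial_last_bin: bool = False
    filtered: bool = False

    def __post_init__(self) -> None:
        n = len(self.bin_start_s)
        for name in ("distance_cm", "activity", "upper_zone_detected"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch for {name}")

    def __len__(self) -> int:
        return len(self.bin_start_s)

    @property
    def end_s(self) -> float:
        return float(self.bin_start_s[-1] + self.bin_width_s)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "treatment_label": self.treatment_label,
                "bin_start_s": self.bin_start_s,
                "distance_cm": self.distance_cm,
                "activity": self.activity,
                "upper_zone_detected": self.upper_zone_detected,
            }
        )


def binned_to_dataframe(binned_list: list[BinnedSeries]) -> pd.DataFrame:
    return pd.concat([b.to_dataframe() for b in binned_list], ignore_index=True)


def binned_from_dataframe(
    df: pd.DataFrame, bin_width_s: float, assay_id: str = ""
) -> list[BinnedSeries]:
    out = []
    for ind, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("bin_start_s")
        label = (
            str(grp["treatment_label"].iloc[0]) if "treatment_label" in grp else ""
        )
        out.append(
            BinnedSeries(
                individual_id=str(ind),
                assay_id=assay_id,
                treatment_label=label,
                bin_width_s=bin_width_s,
                bin_start_s=grp["bin_start_s"].to_numpy(float),
                distance_cm=grp["distance_cm"].to_numpy(float),
                activity=grp["activity"].to_numpy(float),
                upper_zone_detected=grp["upper_zone_detected"].to_numpy(bool),
            )
        )
    return out


@dataclass(frozen=True)
class NoiseProfile:
    """Assay-level background maxima measured in a quiescent window."""

    window_start_s: float
    window_end_s: float
    max_distance_cm: float
    max_activity: float

    def __post_init__(self) -> None:
        if self.window_end_s <= self.window_start_s:
            raise ValueError("quiescent window must have positive length")
        if self.max_distance_cm < 0 or self.max_activity < 0:
            raise ValueError("noise maxima must be non-negative")

    def to_dict(self) -> dict:
        return {
            "window_start_s": self.window_start_s,
            "window_end_s": self.window_end_s,
            "max_distance_cm": self.max_distance_cm,
            "max_activity": self.max_activity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseProfile":
        return cls(
            d["window_start_s"],
            d["window_end_s"],
            d["max_distance_cm"],
            d["max_activity"],
        )


def bin_series(series: TrackSeries, bin_width_s: float = DEFAULT_BIN_WIDTH_S) -> BinnedSeries:
    """Sum distance and activity into half-open bins; flag upper-zone bins.

    A bin's upper flag is true iff any sample in it was detected in the upper
    zone.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    if len(series) == 0:
        raise ValueError("empty series")
    k = np.floor(series.time_s / bin_width_s).astype(int)
    n_bins = int(k[-1]) + 1
    dist = np.bincount(k, weights=series.distance_cm, minlength=n_bins)
    act = np.bincount(k, weights=series.activity, minlength=n_bins)
    upper = (
        np.bincount(
            k, weights=(series.zone == ZONE_UPPER).astype(float), minlength=n_bins
        )
        > 0
    )
    duration = series.time_s[-1] + 1.0 / series.frame_rate_hz
    partial = duration < n_bins * bin_width_s - 1e-9
    return BinnedSeries(
        individual_id=series.individual_id,
        assay_id=series.assay_id,
        treatment_label=series.treatment_label,
        bin_width_s=bin_width_s,
        bin_start_s=np.arange(n_bins) * bin_width_s,
        distance_cm=dist,
        activity=act,
        upper_zone_detected=upper,
        partial_last_bin=bool(partial),
    )


def _window_mask(b: BinnedSeries, start_s: float, end_s: float) -> np.ndarray:
    return (b.bin_start_s < end_s) & (b.bin_start_s + b.bin_width_s > start_s)


def quantify_noise(
    binned_list: list[BinnedSeries],
    window: tuple[float, float],
    activity_ceiling: float | None = None,
) -> NoiseProfile:
    """Maximum binned distance and activity over all individuals in a window.

    The window is the analyst-declared quiescent span of a static
    high-temperature assay. As a sanity check, the window's mean activity
    must stay below ``activity_ceiling``; the default ceiling is the mean
    activity over the whole assay — a quiescent window cannot be busier than
    the recording at large.
    """
    start_s, end_s = window
    if end_s <= start_s:
        raise ValueError("window must have positive length")
    max_d = 0.0
    max_a = 0.0
    in_window_sum = 0.0
    in_window_n = 0
    total_sum = 0.0
    total_n = 0
    any_bins = False
    for b in binned_list:
        if end_s > b.end_s + 1e-9 or start_s < 0:
            raise ValueError(
                f"window [{start_s}, {end_s}] exceeds assay duration for "
                f"{b.individual_id!r}"
            )
        m = _window_mask(b, start_s, end_s)
        if m.any():
            any_bins = True
            max_d = max(max_d, float(b.distance_cm[m].max()))
            max_a = max(max_a, float(b.activity[m].max()))
            in_window_sum += float(b.activity[m].sum())
            in_window_n += int(m.sum())
        total_sum += float(b.activity.sum())
        total_n += len(b)
    if not any_bins:
        raise ValueError("no bins intersect the quiescent window")
    ceiling = (
        activity_ceiling if activity_ceiling is not None else total_sum / total_n
    )
    window_mean = in_window_sum / in_window_n
    if window_mean > ceiling:
        raise ValueError(
            f"quiescent window looks active (mean activity {window_mean:.4g} "
            f"> ceiling {ceiling:.4g}); choose a window after all real "
            "activity has ceased"
        )
    return NoiseProfile(start_s, end_s, max_d, max_a)


def apply_noise_filter(binned: BinnedSeries, profile: NoiseProfile) -> BinnedSeries:
    """Subtract the noise maxima from every bin, clipping at zero.

    Zone flags are untouched: the filter corrects motion signals, not
    positions. A zero profile is the identity.
    """
    return BinnedSeries(
        individual_id=binned.individual_id,
        assay_id=binned.assay_id,
        treatment_label=binned.treatment_label,
        bin_width_s=binned.bin_width_s,
        bin_start_s=binned.bin_start_s.copy(),
        distance_cm=np.maximum(0.0, binned.distance_cm - profile.max_distance_cm),
        activity=np.maximum(0.0, binned.activity - profile.max_activity),
        upper_zone_detected=binned.upper_zone_detected.copy(),
        partial_last_bin=binned.partial_last_bin,
        filtered=True,
    )


def total_distance(binned: BinnedSeries) -> float:
    """Distance moved summed over the entire assay (cm)."""
    return float(binned.distance_cm.sum())
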