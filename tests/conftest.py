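import numpy as np
import pytest

from thermapheno.core import CalibrationScale
from thermapheno.signal import BinnedSeries
from thermapheno.thermal import AssayConfig
from thermapheno.tracking import TrackSeries, VialROI


@pytest.fixture
def cal():
    return CalibrationScale(pixels_per_mm=3.0)


@pytest.fixture
def vial():
    return VialROI(vial_id="V01", bbox_px=(4, 8, 124, 48), middle_line_y_px=64.0)


@pytest.fixture
def short_static_high():
    return AssayConfig(
        species_label="test",
        assay_type="static_high",
        duration_s=600.0,
        static_temp_C=46.5,
    )


@pytest.fixture
def short_static_low():
    return AssayConfig(
        species_label="test",
        assay_type="static_low",
        duration_s=1800.0,
        coma_induction=(0.0, 7200.0),
        recovery_temp_C=27.0,
    )


@pytest.fixture
def short_dynamic():
    return AssayConfig(
        species_label="test",
        assay_type="dynamic",
        duration_s=1200.0,
        start_temp_C=27.0,
        ramp_rate_C_per_min=0.2,
    )


def make_binned(
    distance,
    activity=None,
    upper=None,
    bin_width_s=15.0,
    individual_id="F1",
    treatment="control",
):
    """Hand-built binned series for unit tests."""
    distance = np.asarray(distance, dtype=float)
    n = len(distance)
    activity = (
        np.asarray(activity, dtype=float) if activity is not None else distance.copy()
    )
    upper = (
        np.asarray(upper, dtype=bool) if upper is not None else np.zeros(n, dtype=bool)
    )
    return BinnedSeries(
        individual_id=individual_id,
        assay_id="test",
        treatment_label=treatment,
        bin_width_s=bin_width_s,
        bin_start_s=np.arange(n) * bin_width_s,
        distance_cm=distance,
        activity=activity,
        upper_zone_detected=upper,
    )


def make_track(
    time_s,
    x_mm,
    y_mm,
    distance_cm=None,
    activity=None,
    zone=None,
    frame_rate_hz=5.0,
    individual_id="F1",
):
    """Hand-built track series for unit tests."""
    time_s = np.asarray(time_s, dtype=float)
    n = len(time_s)
    x_mm = np.asarray(x_mm, dtype=float)
    y_mm = np.asarray(y_mm, dtype=float)
    if distance_cm is None:
        distance_cm = np.zeros(n)
        distance_cm[1:] = np.hypot(np.diff(x_mm), np.diff(y_mm)) / 10.0
    if activity is None:
        activity = (np.asarray(distance_cm) > 0).astype(float) * 0.05
    if zone is None:
        zone = np.array(["lower"] * n, dtype=object)
    return TrackSeries(
        individual_id=individual_id,
        assay_id="test",
        treatment_label="control",
        frame_rate_hz=frame_rate_hz,
        time_s=time_s,
        x_mm=x_mm,
        y_mm=y_mm,
        distance_cm=np.asarray(distance_cm, dtype=float),
        activity=np.asarray(activity, dtype=float),
        zone=np.asarray(zone, dtype=object),
    )
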