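"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here: backlit well-plate
images of larvae (elliptical silhouettes), per-vial fly trajectories under
the three assay schedules (chill-coma recovery, static heat knockdown,
temperature ramp), signal-level noise injection mimicking bubbles and
lighting flicker, minute-resolution temperature-logger traces, and paired
mass–area tables. Every artifact carries machine-readable truth so any
downstream stage can be scored without re-derivation, and identical seeds
yield bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ZONE_LOWER, ZONE_UPPER, CalibrationScale
from .size import PlateLayout, Well
from .thermal import STATIC_HIGH, STATIC_LOW, AssayConfig, TemperatureLog
from .tracking import TrackSeries, VialROI

# ---------------------------------------------------------------------------
# Plate rendering


@dataclass(frozen=True)
class LarvaSpec:
    """An elliptical larva silhouette inside one well.

    Backlit larvae are effectively binary silhouettes, so a uniform-interior
    ellipse is rendered. True area π·a·b (px²) is the ground truth.
    """

    well_id: str
    center_px: tuple[float, float]  # (row, col)
    semi_axes_px: tuple[float, float]  # (a, b), a = major
    orientation_rad: float
    intensity_offset: float = 120.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes_px
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        if self.intensity_offset <= 0:
            raise ValueError("intensity_offset must be positive (darker than backlight)")

    @property
    def true_area_px2(self) -> float:
        a, b = self.semi_axes_px
        return math.pi * a * b


def _check_larva_in_well(larva: LarvaSpec, well: Well) -> None:
    a, b = larva.semi_axes_px
    d = math.hypot(
        larva.center_px[0] - well.center_px[0], larva.center_px[1] - well.center_px[1]
    )
    if d + max(a, b) > well.radius_px:
        raise ValueError(f"larva does not fit inside well {well.well_id!r}")


def _paint_ellipse(img: np.ndarray, larva: LarvaSpec, value: float) -> None:
    cy, cx = larva.center_px
    a, b = larva.semi_axes_px
    r = max(a, b) + 1.0
    r0, r1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
    c0, c1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dy, dx = rows - cy, cols - cx
    ct, st = math.cos(larva.orientation_rad), math.sin(larva.orientation_rad)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[r0:r1, c0:c1][inside] = value


def render_plate_image(
    layout: PlateLayout,
    larvae: list[LarvaSpec],
    cal: CalibrationScale,
    backlight_level: float = 220.0,
):
    """Render one plate frame plus its empty-plate reference.

    Returns ``(frame, reference, truth)`` — uint8 images and a per-larva
    ground-truth table (well_id, true_area_px2, true_area_mm2). With an empty
    larva list the frame equals the reference pixel for pixel.
    """
    wells = {w.well_id: w for w in layout.wells}
    seen: set[str] = set()
    for larva in larvae:
        if larva.well_id not in wells:
            raise ValueError(f"unknown well {larva.well_id!r}")
        if larva.well_id in seen:
            raise ValueError(f"more than one larva in well {larva.well_id!r}")
        seen.add(larva.well_id)
        _check_larva_in_well(larva, wells[larva.well_id])
    shape = layout.image_shape()
    reference = np.full(shape, backlight_level, dtype=np.float64)
    frame = reference.copy()
    for larva in larvae:
        _paint_ellipse(frame, larva, backlight_level - larva.intensity_offset)
    truth = pd.DataFrame(
        {
            "well_id": [la.well_id for la in larvae],
            "true_area_px2": [la.true_area_px2 for la in larvae],
            "true_area_mm2": [
                cal.area_px2_to_mm2(la.true_area_px2) for la in larvae
            ],
        }
    )
    return frame.astype(np.uint8), reference.astype(np.uint8), truth


def render_plate_acquisition(
    layout: PlateLayout,
    larvae: list[LarvaSpec],
    cal: CalibrationScale,
    n_frames: int,
    pose_jitter_px: float = 0.5,
    orientation_jitter_rad: float = 0.05,
    backlight_level: float = 220.0,
    seed: int = 0,
):
    """A live-imaging acquisition: frames with small pose jitter per larva.

    Jitter shifts centres and orientations but never the true area, so the
    per-frame variation emulates measurement noise of a wriggling larva.
    Returns ``(frames, reference, truth)``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    reference = None
    truth = None
    for _ in range(n_frames):
        jittered = []
        for la in larvae:
            dy, dx = rng.uniform(-pose_jitter_px, pose_jitter_px, size=2)
            dth = rng.uniform(-orientation_jitter_rad, orientation_jitter_rad)
            jittered.append(
                replace(
                    la,
                    center_px=(la.center_px[0] + dy, la.center_px[1] + dx),
                    orientation_rad=la.orientation_rad + dth,
                )
            )
        frame, reference, truth0 = render_plate_image(
            layout, jittered, cal, backlight_level
        )
        frames.append(frame)
        if truth is None:
            truth = pd.DataFrame(
                {
                    "well_id": [la.well_id for la in larvae],
                    "true_area_px2": [la.true_area_px2 for la in larvae],
                    "true_area_mm2": [
                        cal.area_px2_to_mm2(la.true_area_px2) for la in larvae
                    ],
                }
            )
    return frames, reference, truth


def simulate_larval_cohort(
    n: int,
    cal: CalibrationScale,
    allometry: tuple[float, float] = (0.5, 10.0),
    noise_sd: float = 14.6,
    seed: int = 0,
    wells_per_plate: int = 30,
    well_radius_px: float = 45.0,
):
    """A cohort of larvae with allometric mass–area truth, spread over plates.

    Mass (mg) is log-normal; the true silhouette area follows
    ``area = intercept + slope·mass + N(0, noise_sd)`` (floored away from
    degenerate sizes). Ellipse semi-axes realise exactly that area with a
    random aspect ratio. Returns ``(plates, truth)`` where plates is a list
    of ``(layout, larvae)`` and truth has one row per individual.
    """
    rng = np.random.default_rng(seed)
    slope, intercept = allometry
    mass = rng.lognormal(mean=4.6, sigma=0.35, size=n)
    area_mm2 = intercept + slope * mass + rng.normal(0.0, noise_sd, size=n)
    area_mm2 = np.maximum(area_mm2, 5.0)
    ppm = cal.pixels_per_mm
    n_plates = int(np.ceil(n / wells_per_plate))
    plates = []
    rows = []
    for p in range(n_plates):
        layout = PlateLayout.grid(
            n_rows=5, n_cols=wells_per_plate // 5, well_radius_px=well_radius_px
        )
        larvae = []
        for k in range(wells_per_plate):
            i = p * wells_per_plate + k
            if i >= n:
                break
            area_px2 = area_mm2[i] * ppm**2
            aspect = rng.uniform(1.8, 3.2)
            b = math.sqrt(area_px2 / (math.pi * aspect))
            a = aspect * b
            well = layout.wells[k]
            if a > well.radius_px - 3.0:  # too long for the well: shrink aspect
                a = well.radius_px - 3.0
                b = area_px2 / (math.pi * a)
            theta = rng.uniform(0, math.pi)
            larvae.append(
                LarvaSpec(
                    well_id=well.well_id,
                    center_px=well.center_px,
                    semi_axes_px=(a, b),
                    orientation_rad=theta,
                )
            )
            rows.append(
                {
                    "individual_id": f"P{p + 1}{well.well_id}",
                    "plate": p + 1,
                    "well_id": well.well_id,
                    "mass_mg": mass[i],
                    "true_area_mm2": area_mm2[i],
                    "true_area_px2": area_px2,
                }
            )
        plates.append((layout, larvae))
    return plates, pd.DataFrame(rows)


def simulate_replicate_masses(
    mass_mg: np.ndarray, rel_sd: float = 0.002, n_replicates: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Repeated weighings: multiplicative noise around the true mass.

    The tiny default relative error reflects a precision balance, whose
    technical replicates vary far less than image-based area estimates.
    """
    rng = np.random.default_rng(seed)
    mass_mg = np.asarray(mass_mg, dtype=float)
    cols = {
        f"mass_rep{j + 1}_mg": mass_mg * (1.0 + rng.normal(0.0, rel_sd, len(mass_mg)))
        for j in range(n_replicates)
    }
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Mass–area pairs


@dataclass
class MassAreaFixture:
    """Paired (mass, area) table plus the realised Pearson correlation."""

    table: pd.DataFrame
    realized_pearson_r: float
    realized_pearson_p: float


def simulate_mass_area(
    n: int,
    allometry: tuple[float, float] = (0.5, 10.0),
    noise_sd: float = 14.6,
    seed: int = 0,
    mass_lognormal: tuple[float, float] = (4.6, 0.35),
) -> MassAreaFixture:
    """Paired mass (mg) and surface area (mm²) with a linear allometry.

    ``noise_sd = 0`` makes the pairs exactly collinear. The realised Pearson
    r on the generated table is recorded so downstream correlation stages can
    be checked for exact closure.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    slope, intercept = allometry
    mass = rng.lognormal(mean=mass_lognormal[0], sigma=mass_lognormal[1], size=n)
    area = intercept + slope * mass
    if noise_sd > 0:
        area = area + rng.normal(0.0, noise_sd, size=n)
    table = pd.DataFrame({"mass_mg": mass, "area_mm2": area})
    r, p = sps.pearsonr(table["mass_mg"], table["area_mm2"])
    return MassAreaFixture(table=table, realized_pearson_r=float(r), realized_pearson_p=float(p))


# ---------------------------------------------------------------------------
# Trajectory simulation


@dataclass(frozen=True)
class AgentParams:
    """Schedule-driven behaviour of one simulated fly.

    static_low agents are in chill coma until ``coma_end_s`` (infinite =
    never recovers); static_high / dynamic agents move until ``knockdown_s``
    (0 = never moves, None = never knocked down). ``cross_times_s`` schedules
    excursions into the upper half of the vial.
    """

    individual_id: str
    assay_type: str
    coma_end_s: float | None = None
    knockdown_s: float | None = None
    cross_times_s: tuple[float, ...] = ()
    step_scale_cm: float = 0.2
    activity_level: float = 0.05
    treatment_label: str = ""
    seed: int = 0


@dataclass(frozen=True)
class TraitTruth:
    """Ground-truth trait times of one simulated fly (None = never shown)."""

    individual_id: str
    treatment_label: str
    first_movement_s: float | None
    last_movement_s: float | None
    first_middle_cross_s: float | None
    last_middle_cross_s: float | None
    total_distance_cm: float
    scheduled_never_move: bool = False
    scheduled_never_cross: bool = False


def truths_to_dataframe(truths: list[TraitTruth]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truths])


CROSS_DWELL_S = 1.0


def _active_window(params: AgentParams, duration_s: float) -> tuple[float, float]:
    """[start, end) of the moving phase; empty window means never moves."""
    if params.assay_type == STATIC_LOW:
        start = params.coma_end_s if params.coma_end_s is not None else 0.0
        return (start, duration_s + 1e9)  # moves until the recording ends
    kd = params.knockdown_s if params.knockdown_s is not None else duration_s + 1e9
    return (0.0, kd)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    period = 2.0 * (hi - lo)
    y = np.mod(x - lo, period)
    y = np.where(y > (hi - lo), period - y, y)
    return lo + y


def simulate_track(
    params: AgentParams,
    assay: AssayConfig,
    vial: VialROI,
    cal: CalibrationScale,
    frame_rate_hz: float = 5.0,
) -> tuple[TrackSeries, TraitTruth]:
    """Simulate one fly's track under its assay schedule.

    Construction guarantees: zero activity and distance outside the active
    window; strictly positive activity at every frame inside it (the bounded
    random walk never repeats a position); the centroid sits strictly in the
    upper half during each scheduled cross and strictly in the lower half
    otherwise. Ground truth is read off the realised frames.
    """
    fps = frame_rate_hz
    n = int(round(assay.duration_s * fps)) + 1
    t = np.arange(n) / fps
    act_start, act_end = _active_window(params, assay.duration_s)
    for c in params.cross_times_s:
        if not (0.0 <= c <= assay.duration_s):
            raise ValueError(f"cross time {c} outside assay duration")
        if not (act_start <= c and c + CROSS_DWELL_S <= min(act_end, assay.duration_s)):
            raise ValueError(f"cross time {c} outside the agent's active window")

    rng = np.random.default_rng(params.seed)
    ppm = cal.pixels_per_mm
    top, left, bottom, right = vial.bbox_px
    mid = vial.middle_line_y_px
    pad = 2.0
    lo_row, hi_row = mid + pad, bottom - pad  # lower zone band
    up_lo, up_hi = top + pad, mid - 1.0  # upper zone band
    lo_col, hi_col = left + pad, right - pad
    rest = ((lo_row + hi_row) / 2.0, (lo_col + hi_col) / 2.0)

    active = (t >= act_start) & (t < act_end)
    step_px = params.step_scale_cm * 10.0 * ppm
    steps_r = rng.uniform(-1.0, 1.0, n) * step_px
    steps_c = rng.uniform(-1.0, 1.0, n) * step_px
    # bounded walk: reflect the cumulative path into the lower-zone band
    walk_r = _reflect(rest[0] + np.cumsum(steps_r), lo_row, hi_row)
    walk_c = _reflect(rest[1] + np.cumsum(steps_c), lo_col, hi_col)

    row = np.full(n, rest[0])
    col = np.full(n, rest[1])
    row[active] = walk_r[active]
    col[active] = walk_c[active]
    # freeze at the last active position after knockdown
    idx_active = np.flatnonzero(active)
    if len(idx_active) and idx_active[-1] < n - 1:
        last = idx_active[-1]
        row[last + 1 :] = row[last]
        col[last + 1 :] = col[last]

    crossing = np.zeros(n, dtype=bool)
    for c in params.cross_times_s:
        sel = (t >= c) & (t < c + CROSS_DWELL_S) & active
        crossing |= sel
    if np.any(crossing):
        row[crossing] = rng.uniform(up_lo, up_hi, int(crossing.sum()))

    x_mm = col / ppm
    y_mm = row / ppm
    dist = np.zeros(n)
    moved = np.zeros(n, dtype=bool)
    if n > 1:
        step_mm = np.hypot(np.diff(x_mm), np.diff(y_mm))
        dist[1:] = step_mm / 10.0
        moved[1:] = step_mm > 0
    activity = np.where(
        moved, params.activity_level * rng.uniform(0.5, 1.5, n), 0.0
    )
    zone = np.where(row < mid, ZONE_UPPER, ZONE_LOWER).astype(object)

    series = TrackSeries(
        individual_id=params.individual_id,
        assay_id=f"{assay.species_label}:{assay.assay_type}",
        treatment_label=params.treatment_label,
        frame_rate_hz=fps,
        time_s=t,
        x_mm=x_mm,
        y_mm=y_mm,
        distance_cm=dist,
        activity=activity,
        zone=zone,
    )
    mov_idx = np.flatnonzero(activity > 0)
    up_idx = np.flatnonzero(zone == ZONE_UPPER)
    truth = TraitTruth(
        individual_id=params.individual_id,
        treatment_label=params.treatment_label,
        first_movement_s=float(t[mov_idx[0]]) if len(mov_idx) else None,
        last_movement_s=float(t[mov_idx[-1]]) if len(mov_idx) else None,
        first_middle_cross_s=float(t[up_idx[0]]) if len(up_idx) else None,
        last_middle_cross_s=float(t[up_idx[-1]]) if len(up_idx) else None,
        total_distance_cm=float(dist.sum()),
        scheduled_never_move=len(mov_idx) == 0,
        scheduled_never_cross=len(params.cross_times_s) == 0,
    )
    return series, truth


def vial_rack_rois(
    n_vials: int,
    vial_width_px: int = 40,
    vial_height_px: int = 120,
    gap_px: int = 8,
    top_px: int = 4,
    id_prefix: str = "V",
) -> tuple[list[VialROI], tuple[int, int]]:
    """A horizontal rack of vial ROIs plus the enclosing frame shape."""
    rois = []
    for i in range(n_vials):
        left = gap_px + i * (vial_width_px + gap_px)
        rois.append(
            VialROI(
                vial_id=f"{id_prefix}{i + 1:02d}",
                bbox_px=(top_px, left, top_px + vial_height_px, left + vial_width_px),
                middle_line_y_px=top_px + vial_height_px / 2.0,
            )
        )
    shape = (
        top_px + vial_height_px + gap_px,
        gap_px + n_vials * (vial_width_px + gap_px),
    )
    return rois, shape


def render_vial_frames(
    series_list: list[TrackSeries],
    rois: list[VialROI],
    cal: CalibrationScale,
    frame_shape: tuple[int, int],
    fly_radius_px: float = 3.0,
    backlight_level: float = 220.0,
    fly_intensity_offset: float = 120.0,
):
    """Rasterise simulated tracks into backlit frames (one disk per fly).

    Returns ``(frames, reference)``; frames is a uint8 array (n, H, W).
    Disk centres keep sub-pixel precision so rasterised centroids stay within
    a fraction of a pixel of the simulated ones.
    """
    if len(series_list) != len(rois):
        raise ValueError("one series per ROI required")
    n = len(series_list[0])
    if any(len(s) != n for s in series_list):
        raise ValueError("series lengths differ")
    ppm = cal.pixels_per_mm
    reference = np.full(frame_shape, backlight_level, dtype=np.float64)
    frames = np.empty((n, *frame_shape), dtype=np.uint8)
    value = backlight_level - fly_intensity_offset
    r = fly_radius_px
    for i in range(n):
        img = reference.copy()
        for s in series_list:
            if np.isnan(s.x_mm[i]):
                continue
            cy, cx = s.y_mm[i] * ppm, s.x_mm[i] * ppm
            r0, r1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
            c0, c1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
            rows, cols = np.mgrid[r0:r1, c0:c1]
            disk = (rows - cy) ** 2 + (cols - cx) ** 2 <= r * r
            img[r0:r1, c0:c1][disk] = value
        frames[i] = img.astype(np.uint8)
    return frames, reference.astype(np.uint8)


# ---------------------------------------------------------------------------
# Noise injection


@dataclass(frozen=True)
class NoiseInjection:
    """Signal-level artifacts: bubbles (distance + activity spikes) and
    lighting flicker (activity-only blips of fixed amplitude).

    Events of each kind are kept at least ``min_spacing_s`` apart (default:
    one analysis bin), so the injected per-bin totals are bounded — the
    regime a max-subtraction noise filter is designed for. Zero rates and
    amplitudes leave the series untouched. The magnitude model is a stand-in
    for real recording artifacts, not a measurement of them.
    """

    bubble_rate_per_s: float = 0.0
    bubble_magnitude_cm: tuple[float, float] = (0.05, 0.05)
    bubble_activity: tuple[float, float] = (0.01, 0.01)
    flicker_rate_per_s: float = 0.0
    flicker_amplitude: float = 0.0
    min_spacing_s: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bubble_rate_per_s < 0 or self.flicker_rate_per_s < 0:
            raise ValueError("rates must be non-negative")
        if self.flicker_amplitude < 0:
            raise ValueError("flicker_amplitude must be non-negative")
        if self.min_spacing_s < 0:
            raise ValueError("min_spacing_s must be non-negative")


def _sparse_event_frames(
    rng: np.random.Generator, n: int, dt: float, rate_per_s: float, min_spacing_s: float
) -> np.ndarray:
    """Bernoulli event frames thinned to a minimum spacing."""
    hits = np.flatnonzero(rng.random(n) < rate_per_s * dt)
    if min_spacing_s <= 0 or len(hits) == 0:
        return hits
    spacing_frames = min_spacing_s / dt
    kept = [hits[0]]
    for i in hits[1:]:
        if i - kept[-1] >= spacing_frames:
            kept.append(i)
    return np.asarray(kept, dtype=int)


def inject_noise(
    series: TrackSeries, inj: NoiseInjection
) -> tuple[TrackSeries, pd.DataFrame]:
    """Add spurious distance/activity events; ground truth is untouched.

    Returns the corrupted series and an event table (frame_index, time_s,
    kind, distance_added_cm, activity_added) so the filter's effect is
    checkable against exactly what was injected.
    """
    n = len(series)
    dt = 1.0 / series.frame_rate_hz
    rng = np.random.default_rng(inj.seed)
    dist = series.distance_cm.copy()
    act = series.activity.copy()
    events = []
    if inj.bubble_rate_per_s > 0:
        for i in _sparse_event_frames(
            rng, n, dt, inj.bubble_rate_per_s, inj.min_spacing_s
        ):
            d = rng.uniform(*inj.bubble_magnitude_cm)
            a = rng.uniform(*inj.bubble_activity)
            dist[i] += d
            act[i] += a
            events.append((i, series.time_s[i], "bubble", d, a))
    if inj.flicker_rate_per_s > 0 and inj.flicker_amplitude > 0:
        for i in _sparse_event_frames(
            rng, n, dt, inj.flicker_rate_per_s, inj.min_spacing_s
        ):
            act[i] += inj.flicker_amplitude
            events.append((i, series.time_s[i], "flicker", 0.0, inj.flicker_amplitude))
    noisy = TrackSeries(
        individual_id=series.individual_id,
        assay_id=series.assay_id,
        treatment_label=series.treatment_label,
        frame_rate_hz=series.frame_rate_hz,
        time_s=series.time_s.copy(),
        x_mm=series.x_mm.copy(),
        y_mm=series.y_mm.copy(),
        distance_cm=dist,
        activity=act,
        zone=series.zone.copy(),
    )
    ev = pd.DataFrame(
        events,
        columns=["frame_index", "time_s", "kind", "distance_added_cm", "activity_added"],
    )
    return noisy, ev


# ---------------------------------------------------------------------------
# Temperature logs


def make_temperature_log(
    assay: AssayConfig, jitter_sd_C: float = 0.0, seed: int = 0
) -> TemperatureLog:
    """One logger reading per 60 s over the assay duration.

    Dynamic assays follow start + rate·t; static assays are constant; both
    get optional Gaussian jitter.
    """
    if jitter_sd_C < 0:
        raise ValueError("jitter_sd_C must be non-negative")
    t = np.arange(0.0, assay.duration_s + 1e-9, 60.0)
    temp = np.asarray(assay.nominal_temperature(t), dtype=float)
    if jitter_sd_C > 0:
        rng = np.random.default_rng(seed)
        temp = temp + rng.normal(0.0, jitter_sd_C, len(t))
    return TemperatureLog(time_s=t, temp_C=temp)


# ---------------------------------------------------------------------------
# Cohorts and manual annotations

TREATMENTS = ("cold", "control", "warm")

# length of the guaranteed-quiescent tail of a static high recording, from
# which the background-noise window is taken
QUIESCENT_TAIL_S = 300.0

# acclimation shifts: mean schedule parameters per treatment
_COMA_END_MEAN_S = {"cold": 600.0, "control": 900.0, "warm": 1800.0}
_KNOCKDOWN_MEAN_S = {"cold": 500.0, "control": 700.0, "warm": 1000.0}
_CTMAX_MEAN_C = {"cold": 43.5, "control": 44.5, "warm": 45.5}


def make_assay_cohort(
    assay: AssayConfig,
    n_per_treatment: int = 20,
    seed: int = 0,
    n_never_move: int = 1,
    n_never_cross: int = 2,
    step_scale_cm: float = 0.2,
    activity_level: float = 0.05,
) -> list[AgentParams]:
    """A cohort of agents (default 3 × 20 = 60 flies) for one assay.

    Acclimation ('cold'/'control'/'warm') shifts the schedule means the way
    thermal acclimation shifts the real traits. Within each treatment the
    last ``n_never_move`` agents are scheduled never to move and the
    ``n_never_cross`` before them never to cross — the flies a real analysis
    would have to exclude.
    """
    rng = np.random.default_rng(seed)
    agents = []
    dur = assay.duration_s
    for treatment in TREATMENTS:
        for k in range(n_per_treatment):
            ind = f"{assay.assay_type}_{treatment}_{k + 1:02d}"
            never_move = k >= n_per_treatment - n_never_move
            never_cross = (
                not never_move
                and k >= n_per_treatment - n_never_move - n_never_cross
            )
            coma_end = knockdown = None
            if assay.assay_type == STATIC_LOW:
                if never_move:
                    coma_end = math.inf
                else:
                    coma_end = float(
                        np.clip(
                            rng.normal(_COMA_END_MEAN_S[treatment], 120.0),
                            60.0,
                            dur - 600.0,
                        )
                    )
                act_start, act_end = coma_end, dur
            else:
                if never_move:
                    knockdown = 0.0
                elif assay.assay_type == STATIC_HIGH:
                    # knockdown must precede the quiescent calibration window
                    # at the tail of the recording
                    knockdown = float(
                        np.clip(
                            rng.normal(_KNOCKDOWN_MEAN_S[treatment], 100.0),
                            120.0,
                            max(120.0, dur - QUIESCENT_TAIL_S - 150.0),
                        )
                    )
                else:  # dynamic: knockdown when the ramp reaches a critical temp
                    temp = rng.normal(_CTMAX_MEAN_C[treatment], 0.4)
                    knockdown = float(
                        np.clip(
                            (temp - assay.start_temp_C)
                            / assay.ramp_rate_C_per_min
                            * 60.0,
                            120.0,
                            dur - 60.0,
                        )
                    )
                act_start, act_end = 0.0, (knockdown if knockdown else 0.0)
            crosses: tuple[float, ...] = ()
            if not never_move and not never_cross:
                lo = act_start + CROSS_DWELL_S
                hi = min(act_end, dur) - 2.0 * CROSS_DWELL_S
                if hi > lo:
                    n_cross = 1 + rng.poisson(2.0)
                    times = np.sort(rng.uniform(lo, hi, n_cross))
                    # keep crosses at least one dwell apart
                    kept = [times[0]]
                    for c in times[1:]:
                        if c - kept[-1] >= 2.0 * CROSS_DWELL_S:
                            kept.append(c)
                    crosses = tuple(float(c) for c in kept)
            agents.append(
                AgentParams(
                    individual_id=ind,
                    assay_type=assay.assay_type,
                    coma_end_s=coma_end,
                    knockdown_s=knockdown,
                    cross_times_s=crosses,
                    step_scale_cm=step_scale_cm,
                    activity_level=activity_level,
                    treatment_label=treatment,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return agents


def simulate_assay_tracks(
    assay: AssayConfig,
    agents: list[AgentParams],
    cal: CalibrationScale,
    frame_rate_hz: float = 5.0,
    vial_width_px: int = 40,
    vial_height_px: int = 120,
) -> tuple[list[TrackSeries], list[TraitTruth], list[VialROI]]:
    """Simulate every agent of a cohort in its own vial."""
    rois, _ = vial_rack_rois(
        len(agents), vial_width_px=vial_width_px, vial_height_px=vial_height_px
    )
    series, truths = [], []
    for params, roi in zip(agents, rois):
        s, tr = simulate_track(params, assay, roi, cal, frame_rate_hz)
        series.append(s)
        truths.append(tr)
    return series, truths, rois


def simulate_manual_annotations(
    truths: list[TraitTruth],
    traits: tuple[str, ...] = (
        "first_movement",
        "last_movement",
        "first_middle_cross",
        "last_middle_cross",
    ),
    observer_sd_s: float = 5.0,
    observer_bias_s: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a human observer scoring the videos: truth plus reaction noise.

    Flies that never showed a trait get an empty time (the manual channel's
    exclusion). Output matches the manual-annotation CSV schema.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tr in truths:
        for trait in traits:
            val = getattr(tr, trait + "_s")
            if val is None:
                rows.append(
                    {
                        "individual_id": tr.individual_id,
                        "trait": trait,
                        "time_s": np.nan,
                        "treatment_label": tr.treatment_label,
                    }
                )
            else:
                noisy = max(0.0, val + observer_bias_s + rng.normal(0.0, observer_sd_s))
                rows.append(
                    {
                        "individual_id": tr.individual_id,
                        "trait": trait,
                        "time_s": noisy,
                        "treatment_label": tr.treatment_label,
                    }
                )
    return pd.DataFrame(rows)
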