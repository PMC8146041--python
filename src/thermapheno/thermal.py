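"""Assay definitions and the time→temperature mapping for ramping assays.

In a dynamic (ramping) assay the water-bath temperature rises at a nominal
constant rate (0.2 °C min⁻¹ in the default protocols) while a logger records
one reading per minute. CTmax endpoints are obtained by fitting an ordinary
least-squares line to the logger trace and evaluating it at the trait time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STATIC_LOW = "static_low"
STATIC_HIGH = "static_high"
DYNAMIC = "dynamic"
ASSAY_TYPES = (STATIC_LOW, STATIC_HIGH, DYNAMIC)


@dataclass(frozen=True)
class AssayConfig:
    """One thermal-stress assay protocol.

    static_low: chill-coma induction (``coma_induction`` = (temp_C,
    duration_s)) followed by recovery at ``recovery_temp_C``; the recording
    covers the recovery phase. static_high: constant ``static_temp_C``.
    dynamic: ramp from ``start_temp_C`` at ``ramp_rate_C_per_min``.
    """

    species_label: str
    assay_type: str
    duration_s: float
    start_temp_C: float | None = None
    ramp_rate_C_per_min: float | None = None
    static_temp_C: float | None = None
    coma_induction: tuple[float, float] | None = None
    recovery_temp_C: float | None = None

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"unknown assay_type {self.assay_type!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.assay_type == DYNAMIC:
            if self.ramp_rate_C_per_min is None or self.ramp_rate_C_per_min <= 0:
                raise ValueError("dynamic assay requires ramp_rate_C_per_min > 0")
            if self.start_temp_C is None:
                raise ValueError("dynamic assay requires start_temp_C")
        if self.assay_type == STATIC_HIGH and self.static_temp_C is None:
            raise ValueError("static_high assay requires static_temp_C")
        if self.assay_type == STATIC_LOW:
            if self.coma_induction is None:
                raise ValueError("static_low assay requires coma_induction")
            if self.recovery_temp_C is None:
                raise ValueError("static_low assay requires recovery_temp_C")

    def nominal_temperature(self, t_s: float | np.ndarray):
        """Protocol temperature at time ``t_s`` from the recording start."""
        if self.assay_type == DYNAMIC:
            return self.start_temp_C + self.ramp_rate_C_per_min / 60.0 * np.asarray(
                t_s, dtype=float
            )
        if self.assay_type == STATIC_HIGH:
            return np.full_like(np.asarray(t_s, dtype=float), self.static_temp_C)
        return np.full_like(np.asarray(t_s, dtype=float), self.recovery_temp_C)


def default_assays(
    species_label: str = "black_soldier_fly",
    recovery_temp_C: float = 27.0,
    static_temp_C: float = 46.5,
    ramp_start_C: float = 27.0,
) -> dict[str, AssayConfig]:
    """The three default protocols: chill-coma recovery (CCRT, static low),
    heat knockdown (HKDT, static high 46.5 °C) and CTmax (ramp 0.2 °C min⁻¹
    from 27 °C). Recording durations are desk-scale defaults."""
    return {
        STATIC_LOW: AssayConfig(
            species_label=species_label,
            assay_type=STATIC_LOW,
            duration_s=3600.0,
            coma_induction=(0.0, 7200.0),
            recovery_temp_C=recovery_temp_C,
        ),
        STATIC_HIGH: AssayConfig(
            species_label=species_label,
            assay_type=STATIC_HIGH,
            duration_s=1800.0,
            static_temp_C=static_temp_C,
        ),
        DYNAMIC: AssayConfig(
            species_label=species_label,
            assay_type=DYNAMIC,
            duration_s=6600.0,
            start_temp_C=ramp_start_C,
            ramp_rate_C_per_min=0.2,
        ),
    }


@dataclass
class TemperatureLog:
    """Logger trace: ordered (time_s, temp_C) readings, nominally 60 s apart."""

    time_s: np.ndarray
    temp_C: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temp_C = np.asarray(self.temp_C, dtype=float)
        if len(self.time_s) != len(self.temp_C):
            raise ValueError("time and temperature arrays differ in length")
        if len(self.time_s) > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("logger time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "temp_C": self.temp_C})

    @classmethod
    def from_csv(cls, path) -> "TemperatureLog":
        df = pd.read_csv(path, comment="#")
        return cls(df["time_s"].to_numpy(), df["temp_C"].to_numpy())

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class RampModel:
    """Fitted linear time→temperature map: T(t) = intercept + slope·t."""

    slope_C_per_s: float
    intercept_C: float
    r_squared: float
    n_points: int
    t_max_s: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("RampModel needs at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def slope_C_per_min(self) -> float:
        return self.slope_C_per_s * 60.0


def fit_ramp(
    log: TemperatureLog,
    t_start_s: float | None = None,
    t_end_s: float | None = None,
) -> RampModel:
    """OLS fit of temperature on time over the (optionally windowed) trace.

    A constant-temperature trace yields slope 0 and r² defined as 0 (with a
    warning) to avoid the 0/0 in the usual definition.
    """
    t, y = log.time_s, log.temp_C
    if t_start_s is not None or t_end_s is not None:
        lo = -np.inf if t_start_s is None else t_start_s
        hi = np.inf if t_end_s is None else t_end_s
        keep = (t >= lo) & (t <= hi)
        t, y = t[keep], y[keep]
    if len(t) < 2:
        raise ValueError("need at least 2 readings to fit a ramp")
    if np.ptp(t) == 0:
        raise ValueError("zero variance in time")
    if np.ptp(y) == 0:
        warnings.warn("constant-temperature log: defining r² = 0", stacklevel=2)
        return RampModel(0.0, float(y[0]), 0.0, len(t), float(t[-1]))
    res = stats.linregress(t, y)
    r2 = min(1.0, float(res.rvalue) ** 2)
    return RampModel(float(res.slope), float(res.intercept), r2, len(t), float(t[-1]))


def time_to_temperature(t_s: float | np.ndarray, model: RampModel):
    """Map a trait time to the fitted water temperature."""
    return model.intercept_C + model.slope_C_per_s * np.asarray(t_s, dtype=float)


def annotate_ctmax(records: list, model: RampModel, assay: AssayConfig | None = None):
    """Attach temperatures to defined trait times (dynamic assays only).

    Excluded / non-evaluable records pass through unchanged. Times beyond the
    last logger reading are extrapolated and logged: knockdown can postdate
    the final reading.
    """
    if assay is not None and assay.assay_type != DYNAMIC:
        raise ValueError("CTmax temperatures only apply to dynamic assays")
    out = []
    for rec in records:
        if rec.time_s is None:
            out.append(rec)
            continue
        if rec.time_s > model.t_max_s:
            logger.info(
                "extrapolating beyond last logger reading (%.0f s > %.0f s) for %s",
                rec.time_s,
                model.t_max_s,
                rec.individual_id,
            )
        temp = float(time_to_temperature(rec.time_s, model))
        out.append(replace(rec, temperature_C=temp))
    return out
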