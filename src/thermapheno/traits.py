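"""Endpoint trait extraction from filtered, binned track series.

Four traits describe the thermal-stress endpoints: first/last movement (the
first/last non-zero activity bin — chill-coma recovery and heat coma/death)
and first/last middle cross (the first/last bin with an upper-zone detection
— unimpaired vertical locomotion). Flies that never move or never cross are
excluded in-band with a reason code, so downstream exclusion counts stay
reproducible. A truncation rule handles recordings that end early: traits
whose defining event could postdate the cutoff become non-evaluable.

Manual observations enter through the same record type as a parallel method
channel; they are ingested as given, never recomputed — the observer scored
appendage movements and whole-body crosses no centroid signal can replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .signal import BinnedSeries

TRAITS = (
    "first_movement",
    "last_movement",
    "first_middle_cross",
    "last_middle_cross",
)
METHOD_AUTOMATED = "automated"
METHOD_MANUAL = "manual"

STATUS_OK = "ok"
STATUS_EXCLUDED = "excluded"
STATUS_NON_EVALUABLE = "non_evaluable"

REASON_NO_MOVEMENT = "no movement"
REASON_NO_CROSS = "no middle cross"
REASON_TRUNCATED = "truncated recording"


@dataclass(frozen=True)
class TraitRecord:
    """One (individual, method, trait) observation.

    ``time_s`` is None exactly when the record is excluded or non-evaluable;
    the trait timestamp is the start of the defining bin (conservative and
    deterministic).
    """

    individual_id: str
    method: str
    trait: str
    time_s: float | None
    treatment_label: str = ""
    temperature_C: float | None = None
    status: str = STATUS_OK
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.method not in (METHOD_AUTOMATED, METHOD_MANUAL):
            raise ValueError(f"unknown method {self.method!r}")
        if self.time_s is not None and self.time_s < 0:
            raise ValueError("trait time must be non-negative")
        if self.status == STATUS_OK and self.time_s is None:
            raise ValueError("ok record must carry a time")
        if self.status != STATUS_OK and self.reason is None:
            raise ValueError("excluded/non-evaluable record must carry a reason")

    @property
    def defined(self) -> bool:
        return self.status == STATUS_OK


@dataclass(frozen=True)
class TruncationRule:
    """Recording cut off at ``cutoff_s``: traits whose defining event could
    lie beyond the cutoff cannot be evaluated."""

    cutoff_s: float
    affected_traits: tuple[str, ...] = ("last_movement", "last_middle_cross")

    def __post_init__(self) -> None:
        if self.cutoff_s <= 0:
            raise ValueError("cutoff must be positive")
        for t in self.affected_traits:
            if t not in TRAITS:
                raise ValueError(f"unknown trait {t!r}")


def first_last_movement(binned: BinnedSeries, which: str) -> TraitRecord:
    """Time of the first/last bin with non-zero activity (bin start).

    An all-zero series means the fly never moved and is excluded.
    """
    if which not in ("first", "last"):
        raise ValueError("which must be 'first' or 'last'")
    trait = f"{which}_movement"
    idx = np.flatnonzero(binned.activity > 0)
    if len(idx) == 0:
        return TraitRecord(
            individual_id=binned.individual_id,
            method=METHOD_AUTOMATED,
            trait=trait,
            time_s=None,
            treatment_label=binned.treatment_label,
            status=STATUS_EXCLUDED,
            reason=REASON_NO_MOVEMENT,
        )
    i = idx[0] if which == "first" else idx[-1]
    return TraitRecord(
        individual_id=binned.individual_id,
        method=METHOD_AUTOMATED,
        trait=trait,
        time_s=float(binned.bin_start_s[i]),
        treatment_label=binned.treatment_label,
    )


def first_last_middle_cross(binned: BinnedSeries, which: str) -> TraitRecord:
    """Time of the first/last bin with an upper-zone detection (bin start)."""
    if which not in ("first", "last"):
        raise ValueError("which must be 'first' or 'last'")
    trait = f"{which}_middle_cross"
    idx = np.flatnonzero(binned.upper_zone_detected)
    if len(idx) == 0:
        return TraitRecord(
            individual_id=binned.individual_id,
            method=METHOD_AUTOMATED,
            trait=trait,
            time_s=None,
            treatment_label=binned.treatment_label,
            status=STATUS_EXCLUDED,
            reason=REASON_NO_CROSS,
        )
    i = idx[0] if which == "first" else idx[-1]
    return TraitRecord(
        individual_id=binned.individual_id,
        method=METHOD_AUTOMATED,
        trait=trait,
        time_s=float(binned.bin_start_s[i]),
        treatment_label=binned.treatment_label,
    )


def extract_traits(
    binned: BinnedSeries, traits: tuple[str, ...] = TRAITS
) -> list[TraitRecord]:
    """All requested endpoint traits for one individual."""
    out = []
    for t in traits:
        which, _, kind = t.partition("_")
        if t.endswith("movement"):
            out.append(first_last_movement(binned, which))
        else:
            out.append(first_last_middle_cross(binned, which))
    return out


def apply_truncation(
    records: list[TraitRecord], rule: TruncationRule, series_end_s: float
) -> list[TraitRecord]:
    """Apply an early-recording-end rule to extracted records.

    When the data end at the cutoff, last movement cannot be evaluated for
    anyone (movement could always recur later). Last middle cross is kept for
    individuals whose event precedes the cutoff; individuals whose event does
    not provably precede it become non-evaluable. A cutoff at or beyond the
    true series end changes nothing.
    """
    if rule.cutoff_s >= series_end_s:
        return list(records)
    out = []
    for rec in records:
        if rec.trait not in rule.affected_traits or not rec.defined:
            out.append(rec)
            continue
        if rec.trait == "last_movement" or rec.time_s >= rule.cutoff_s:
            out.append(
                replace(
                    rec,
                    time_s=None,
                    status=STATUS_NON_EVALUABLE,
                    reason=REASON_TRUNCATED,
                )
            )
        else:
            out.append(rec)
    return out


def records_to_dataframe(records: list[TraitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "method": r.method,
                "trait": r.trait,
                "time_s": r.time_s if r.time_s is not None else np.nan,
                "treatment_label": r.treatment_label,
                "temperature_C": r.temperature_C
                if r.temperature_C is not None
                else np.nan,
                "status": r.status,
                "reason": r.reason or "",
            }
            for r in records
        ]
    )


def load_manual_annotations(table) -> list[TraitRecord]:
    """Ingest a manual-annotation table as trait records (method = manual).

    Accepts a DataFrame or a CSV path with columns individual_id, trait,
    time_s (empty / NA = the observer excluded the fly) and optionally
    treatment_label. Times must be in seconds. Duplicate (individual, trait)
    rows signal a corrupt annotation file and raise.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, comment="#")
    required = {"individual_id", "trait", "time_s"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["individual_id", "trait"])
    if dup.any():
        bad = table.loc[dup, ["individual_id", "trait"]].iloc[0]
        raise ValueError(
            f"duplicate annotation for ({bad['individual_id']!r}, {bad['trait']!r})"
        )
    records = []
    for _, row in table.iterrows():
        trait = str(row["trait"])
        if trait not in TRAITS:
            raise ValueError(f"unknown trait label {trait!r}")
        label = str(row.get("treatment_label", "") or "")
        raw = row["time_s"]
        is_na = pd.isna(raw) or (isinstance(raw, str) and raw.strip().upper() in ("", "NA"))
        if is_na:
            reason = (
                REASON_NO_MOVEMENT if trait.endswith("movement") else REASON_NO_CROSS
            )
            records.append(
                TraitRecord(
                    individual_id=str(row["individual_id"]),
                    method=METHOD_MANUAL,
                    trait=trait,
                    time_s=None,
                    treatment_label=label,
                    status=STATUS_EXCLUDED,
                    reason=reason,
                )
            )
        else:
            t = float(raw)
            if t < 0:
                raise ValueError(
                    f"negative time for ({row['individual_id']!r}, {trait!r})"
                )
            records.append(
                TraitRecord(
                    individual_id=str(row["individual_id"]),
                    method=METHOD_MANUAL,
                    trait=trait,
                    time_s=t,
                    treatment_label=label,
                )
            )
    return records
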