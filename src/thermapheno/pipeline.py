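"""End-to-end orchestration: simulate → track/bin/filter → traits → stats.

One JSON-able config drives a full reproducible run. Every stage's outputs
are written under the run directory and recorded, with SHA-256 checksums, in
a manifest; deterministic stages reproduce identical checksums under the same
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import signal as sig
from . import stats as st
from . import synthetic as syn
from .core import CalibrationScale
from .size import acquire_mean_area, measure_replicates
from .thermal import DYNAMIC, STATIC_HIGH, AssayConfig, default_assays, fit_ramp
from .traits import (
    TruncationRule,
    apply_truncation,
    extract_traits,
    load_manual_annotations,
    records_to_dataframe,
)
from .thermal import annotate_ctmax
from .tracking import tracks_to_dataframe

logger = logging.getLogger(__name__)


def _stable_offset(name: str, mod: int = 10000) -> int:
    # process-independent substitute for hash(): manifests must reproduce
    return zlib.crc32(name.encode()) % mod


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serialisable to JSON."""

    seed: int = 0
    species_label: str = "black_soldier_fly"
    n_per_treatment: int = 2
    frame_rate_hz: float = 5.0
    pixels_per_mm: float = 3.0
    bin_width_s: float = 15.0
    noise_window_s: tuple[float, float] | None = None
    truncation_cutoff_s: float | None = 1500.0
    n_larvae: int = 30
    n_size_replicates: int = 3
    frames_per_acquisition: int = 3
    inject_noise: bool = False
    bubble_rate_per_s: float = 0.02
    flicker_rate_per_s: float = 0.01
    flicker_amplitude: float = 0.01
    anova_ss_type: int = 2
    out_dir: str = "thermapheno_run"
    assays: dict = field(default_factory=dict)  # overrides of default_assays()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if cfg.noise_window_s is not None:
            cfg.noise_window_s = tuple(cfg.noise_window_s)
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def resolved_assays(self) -> dict[str, AssayConfig]:
        base = default_assays(self.species_label)
        out = {}
        for name, assay in base.items():
            if name in self.assays:
                d = asdict(assay)
                d.update(self.assays[name])
                if d.get("coma_induction") is not None:
                    d["coma_induction"] = tuple(d["coma_induction"])
                out[name] = AssayConfig(**d)
            else:
                out[name] = assay
        return out


def demo_config(out_dir: str = "thermapheno_demo", seed: int = 0) -> RunConfig:
    """A small complete run: 6 flies per assay, 30 larvae, one plate."""
    return RunConfig(seed=seed, out_dir=out_dir)


def validate_config(config: RunConfig) -> list[str]:
    """All configuration errors at once (empty list = valid)."""
    errors: list[str] = []
    if config.seed < 0:
        errors.append("seed must be non-negative")
    if config.n_per_treatment < 1:
        errors.append("n_per_treatment must be >= 1")
    if config.frame_rate_hz <= 0:
        errors.append("frame_rate_hz must be positive")
    if config.pixels_per_mm <= 0:
        errors.append("pixels_per_mm must be positive")
    if config.bin_width_s <= 0:
        errors.append("bin_width_s must be positive")
    if config.n_larvae < 1:
        errors.append("n_larvae must be >= 1")
    if config.n_size_replicates < 1:
        errors.append("n_size_replicates must be >= 1")
    try:
        assays = config.resolved_assays()
    except (ValueError, TypeError) as exc:
        errors.append(f"invalid assay config: {exc}")
        assays = None
    if assays is not None:
        if config.noise_window_s is not None:
            lo, hi = config.noise_window_s
            dur = assays[STATIC_HIGH].duration_s
            if not (0 <= lo < hi <= dur):
                errors.append(
                    f"noise_window_s [{lo}, {hi}] outside static_high duration {dur}"
                )
        if config.truncation_cutoff_s is not None and config.truncation_cutoff_s <= 0:
            errors.append("truncation_cutoff_s must be positive")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# thermapheno seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


class _Manifest:
    def __init__(self, seed: int):
        self.data = {"seed": seed, "stages": {}}

    def record(self, stage: str, outputs: list[Path], t0: float) -> None:
        self.data["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
            "elapsed_s": round(time.monotonic() - t0, 3),
        }
        logger.info("stage %s done (%.2fs)", stage, time.monotonic() - t0)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


def _anova_to_dict(tab: st.AnovaTable) -> dict:
    terms = {}
    for term, row in tab.table.iterrows():
        terms[str(term).strip()] = {
            "df": float(row["df"]),
            "sum_sq": float(row["sum_sq"]),
            "F": None if pd.isna(row["F"]) else float(row["F"]),
            "p": None if pd.isna(row["PR(>F)"]) else float(row["PR(>F)"]),
        }
    return {
        "terms": terms,
        "df_resid": tab.df_resid,
        "ss_type": tab.ss_type,
        "transform": tab.transform_applied,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage; returns the manifest dict.

    Stage failure aborts with the failing stage named; outputs written so far
    are retained for inspection.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config.seed)
    cal = CalibrationScale(config.pixels_per_mm)
    assays = config.resolved_assays()
    rng_root = np.random.SeedSequence(config.seed)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("larvae", "tracks", "templog", "noise", "manual", "mass"),
            rng_root.spawn(6),
        )
    }

    stage = "simulate"
    try:
        t0 = time.monotonic()
        outputs: list[Path] = []
        # --- larvae and plates
        plates, larvae_truth = syn.simulate_larval_cohort(
            config.n_larvae, cal, seed=stage_seed["larvae"]
        )
        acq_store: dict[str, list] = {}
        for p, (layout, larvae) in enumerate(plates):
            reps = []
            for rep in range(config.n_size_replicates):
                frames, reference, _truth = syn.render_plate_acquisition(
                    layout,
                    larvae,
                    cal,
                    n_frames=config.frames_per_acquisition,
                    seed=stage_seed["larvae"] + 1000 * (rep + 1) + p,
                )
                reps.append((frames, reference, layout))
                for j, frame in enumerate(frames):
                    fp = out / f"plate{p + 1}_rep{rep + 1}_frame{j:03d}.png"
                    iio.imwrite(fp, frame)
                    outputs.append(fp)
            ref_path = out / f"plate{p + 1}_reference.png"
            iio.imwrite(ref_path, reps[0][1])
            outputs.append(ref_path)
            acq_store[f"plate{p + 1}"] = reps
        _write_csv(larvae_truth, out / "larvae_truth.csv", config.seed)
        outputs.append(out / "larvae_truth.csv")
        masses = syn.simulate_replicate_masses(
            larvae_truth["mass_mg"].to_numpy(), seed=stage_seed["mass"]
        )
        masses.insert(0, "individual_id", larvae_truth["individual_id"])
        _write_csv(masses, out / "masses.csv", config.seed)
        outputs.append(out / "masses.csv")
        # --- tracks, truths, temperature logs
        all_series: dict[str, list] = {}
        all_truths: dict[str, list] = {}
        for name, assay in assays.items():
            agents = syn.make_assay_cohort(
                assay,
                n_per_treatment=config.n_per_treatment,
                seed=stage_seed["tracks"] + _stable_offset(name),
                n_never_move=1 if config.n_per_treatment >= 3 else 0,
                n_never_cross=1 if config.n_per_treatment >= 3 else 0,
            )
            series, truths, _rois = syn.simulate_assay_tracks(
                assay, agents, cal, frame_rate_hz=config.frame_rate_hz
            )
            if config.inject_noise:
                noisy = []
                for i, s in enumerate(series):
                    ns, _ev = syn.inject_noise(
                        s,
                        syn.NoiseInjection(
                            bubble_rate_per_s=config.bubble_rate_per_s,
                            flicker_rate_per_s=config.flicker_rate_per_s,
                            flicker_amplitude=config.flicker_amplitude,
                            seed=stage_seed["noise"] + _stable_offset(name) + i,
                        ),
                    )
                    noisy.append(ns)
                series = noisy
            all_series[name] = series
            all_truths[name] = truths
            df = tracks_to_dataframe(series)
            df["treatment_label"] = df["individual_id"].map(
                {s.individual_id: s.treatment_label for s in series}
            )
            _write_csv(df, out / f"tracks_{name}.csv", config.seed)
            outputs.append(out / f"tracks_{name}.csv")
            _write_csv(
                syn.truths_to_dataframe(truths), out / f"truth_{name}.csv", config.seed
            )
            outputs.append(out / f"truth_{name}.csv")
            log = syn.make_temperature_log(
                assay, jitter_sd_C=0.05, seed=stage_seed["templog"]
            )
            _write_csv(log.to_dataframe(), out / f"templog_{name}.csv", config.seed)
            outputs.append(out / f"templog_{name}.csv")
        manifest.record(stage, outputs, t0)

        # --- size estimation
        stage = "size"
        t0 = time.monotonic()
        outputs = []
        plate_tables = []
        for p in range(len(plates)):
            reps = acq_store[f"plate{p + 1}"]
            acqs = [
                acquire_mean_area(frames, layout, cal, reference)
                for frames, reference, layout in reps
            ]
            tab = measure_replicates(acqs, id_prefix=f"P{p + 1}")
            plate_tables.append(tab)
        sizes = pd.concat(plate_tables, ignore_index=True)
        sizes = sizes[sizes["individual_id"].isin(larvae_truth["individual_id"])]
        _write_csv(sizes, out / "sizes.csv", config.seed)
        outputs.append(out / "sizes.csv")
        manifest.record(stage, outputs, t0)

        # --- binning and noise filtering
        stage = "bin_filter"
        t0 = time.monotonic()
        outputs = []
        binned: dict[str, list] = {
            name: [sig.bin_series(s, config.bin_width_s) for s in series]
            for name, series in all_series.items()
        }
        window = config.noise_window_s
        if window is None:
            dur = assays[STATIC_HIGH].duration_s
            window = (dur - 300.0, dur)
        profile = sig.quantify_noise(binned[STATIC_HIGH], window)
        with open(out / "noise_profile.json", "w") as fh:
            json.dump(profile.to_dict(), fh, indent=2, sort_keys=True)
        outputs.append(out / "noise_profile.json")
        filtered = {
            name: [sig.apply_noise_filter(b, profile) for b in blist]
            for name, blist in binned.items()
        }
        for name, blist in filtered.items():
            _write_csv(
                sig.binned_to_dataframe(blist), out / f"bins_{name}.csv", config.seed
            )
            outputs.append(out / f"bins_{name}.csv")
        manifest.record(stage, outputs, t0)

        # --- trait extraction (automated + manual channel)
        stage = "traits"
        t0 = time.monotonic()
        outputs = []
        all_records: dict[str, list] = {}
        for name, blist in filtered.items():
            records = []
            for b in blist:
                records.extend(extract_traits(b))
            if name == STATIC_HIGH and config.truncation_cutoff_s is not None:
                rule = TruncationRule(cutoff_s=config.truncation_cutoff_s)
                records = apply_truncation(
                    records, rule, series_end_s=assays[name].duration_s
                )
            manual_df = syn.simulate_manual_annotations(
                all_truths[name], seed=stage_seed["manual"] + _stable_offset(name)
            )
            records.extend(load_manual_annotations(manual_df))
            if name == DYNAMIC:
                log = syn.make_temperature_log(
                    assays[name], jitter_sd_C=0.05, seed=stage_seed["templog"]
                )
                model = fit_ramp(log)
                records = annotate_ctmax(records, model, assays[name])
            all_records[name] = records
            _write_csv(
                records_to_dataframe(records), out / f"traits_{name}.csv", config.seed
            )
            outputs.append(out / f"traits_{name}.csv")
        manifest.record(stage, outputs, t0)

        # --- statistics
        stage = "stats"
        t0 = time.monotonic()
        outputs = []
        report: dict = {}
        merged = larvae_truth.merge(sizes, on="individual_id")
        ok = merged["mean_area_mm2"].notna()
        corr, assum = st.route_correlation(
            merged.loc[ok, "mass_mg"], merged.loc[ok, "mean_area_mm2"]
        )
        report["size_agreement"] = {
            "method": corr.method,
            "coefficient": corr.coefficient,
            "r_squared": corr.r_squared,
            "p_value": corr.p_value,
            "n": corr.n,
            "pearson_r": corr.pearson_r,
            "spearman_r": corr.spearman_r,
            "assumptions": {
                "normality_ok": assum.normality_ok,
                "n_outliers": len(assum.outlier_ids),
                "homoscedasticity_ok": assum.homoscedasticity_ok,
                "linearity_ok": assum.linearity_ok,
            },
        }
        mass_cols = [c for c in masses.columns if c.startswith("mass_rep")]
        cv_manual = (
            masses[mass_cols].std(axis=1, ddof=1)
            / masses[mass_cols].mean(axis=1)
            * 100.0
        )
        cv_df = merged.loc[ok]
        report["cv_comparison"] = st.compare_cv(
            cv_manual[ok.to_numpy()], cv_df["cv_percent"]
        )
        report["assays"] = {}
        for name, records in all_records.items():
            block: dict = {"anova": {}, "total_distance": {}}
            rec_df = records_to_dataframe(records)
            for trait in rec_df["trait"].unique():
                sub = rec_df[(rec_df["trait"] == trait) & (rec_df["status"] == "ok")]
                cells = sub.groupby(["treatment_label", "method"]).size()
                if len(sub) < 6 or (cells < 2).any() or sub["method"].nunique() < 2:
                    block["anova"][trait] = {"skipped": "insufficient data per cell"}
                    continue
                sub = sub.assign(ln_time=st.log1p_transform(sub["time_s"]))
                tab = st.two_way_anova(
                    sub,
                    "ln_time",
                    "treatment_label",
                    "method",
                    typ=config.anova_ss_type,
                    transform_applied="ln(x+1)",
                )
                block["anova"][trait] = _anova_to_dict(tab)
                block.setdefault("se", {})[trait] = {
                    str(k): st.standard_error(g["time_s"])
                    for k, g in sub.groupby(["treatment_label", "method"])
                    if len(g) >= 2
                }
            dist_rows = [
                {
                    "individual_id": b.individual_id,
                    "treatment_label": b.treatment_label,
                    "distance_cm": sig.total_distance(b),
                }
                for b in filtered[name]
            ]
            ddf = pd.DataFrame(dist_rows)
            ddf["ln_distance"] = st.log1p_transform(ddf["distance_cm"])
            sizes_ok = ddf.groupby("treatment_label").size()
            if (sizes_ok >= 2).all() and len(sizes_ok) >= 2:
                dtab = st.one_way_anova(
                    ddf, "ln_distance", "treatment_label", transform_applied="ln(x+1)"
                )
                block["total_distance"]["anova"] = _anova_to_dict(dtab)
            block["total_distance"]["mean_cm_by_treatment"] = (
                ddf.groupby("treatment_label")["distance_cm"].mean().to_dict()
            )
            report["assays"][name] = block
        with open(out / "stats.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        outputs.append(out / "stats.json")
        manifest.record(stage, outputs, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest.data
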