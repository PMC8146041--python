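"""Basic diagnostic plots: binned distance profiles and trait comparisons."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .signal import BinnedSeries


def plot_distance_profiles(
    binned_list: list[BinnedSeries], ax=None, by_treatment: bool = True
):
    """Mean binned distance over time, one line per treatment group."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 4))
    df = pd.concat(
        [
            pd.DataFrame(
                {
                    "bin_start_s": b.bin_start_s,
                    "distance_cm": b.distance_cm,
                    "treatment": b.treatment_label or "all",
                }
            )
            for b in binned_list
        ],
        ignore_index=True,
    )
    key = "treatment" if by_treatment else None
    groups = df.groupby(key) if key else [("all", df)]
    for label, grp in groups:
        prof = grp.groupby("bin_start_s")["distance_cm"].agg(["mean", "sem"])
        ax.plot(prof.index, prof["mean"], label=str(label))
        ax.fill_between(
            prof.index,
            prof["mean"] - prof["sem"].fillna(0),
            prof["mean"] + prof["sem"].fillna(0),
            alpha=0.2,
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("distance moved per bin (cm)")
    ax.legend(title="treatment")
    return ax


def plot_trait_comparison(records_df: pd.DataFrame, trait: str, ax=None):
    """Trait times by treatment, manual vs automated, with mean ± SE."""
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 4))
    sub = records_df[(records_df["trait"] == trait) & (records_df["status"] == "ok")]
    treatments = sorted(sub["treatment_label"].unique())
    offsets = {"manual": -0.15, "automated": 0.15}
    for method, off in offsets.items():
        mm = sub[sub["method"] == method]
        xs, means, sems = [], [], []
        for i, tr in enumerate(treatments):
            vals = mm.loc[mm["treatment_label"] == tr, "time_s"].to_numpy()
            if len(vals) == 0:
                continue
            ax.scatter(
                np.full(len(vals), i + off), vals, s=10, alpha=0.4, label=None
            )
            xs.append(i + off)
            means.append(vals.mean())
            sems.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0)
        ax.errorbar(xs, means, yerr=sems, fmt="o", capsize=4, label=method)
    ax.set_xticks(range(len(treatments)))
    ax.set_xticklabels(treatments)
    ax.set_ylabel(f"{trait} (s)")
    ax.set_xlabel("acclimation treatment")
    ax.legend(title="method")
    return ax
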