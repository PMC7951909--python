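"""Synthetic-data figure analogues of the study-style summaries.

All plots are clearly labelled as phantom data; layout mirrors the
per-database dot-plus-SEM charts, the scan-time scatter with fitted
lines, and the grouped age comparisons.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_age_groups", "plot_database_summary", "plot_scan_time"]


def plot_database_summary(summary: pd.DataFrame, path: str | Path) -> Path:
    """Per-database normalized SNR_CC and CNR with SEM bars, ascending."""
    sub = summary[summary["quantity"].isin(["CC", "CNR"])]
    contrasts = sub["contrast"].unique()
    fig, axes = plt.subplots(
        1, max(len(contrasts), 1), figsize=(5 * max(len(contrasts), 1), 6), squeeze=False
    )
    for ax, contrast in zip(axes[0], contrasts):
        block = sub[sub["contrast"] == contrast]
        dbs = block[block["quantity"] == "CC"]["database"].tolist()
        y = np.arange(len(dbs))
        for quantity, color in (("CC", "black"), ("CNR", "grey")):
            q = block[block["quantity"] == quantity].set_index("database").reindex(dbs)
            ax.errorbar(q["mean"], y, xerr=q["sem"], fmt="o", color=color,
                        label="SNR_CC" if quantity == "CC" else "CNR", capsize=2)
        ax.set_yticks(y, dbs)
        ax.set_xlabel("normalized ratio (1/mm^3)")
        ax.set_title(f"{contrast} (synthetic phantoms)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def plot_scan_time(per_db: pd.DataFrame, path: str | Path) -> Path:
    """Scan time against normalized SNR_CC and against voxel volume."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    markers = {3.0: "o", 7.0: "^"}
    for ax, response, label in (
        (axes[0], "snr_cc", "normalized SNR_CC (1/mm^3)"),
        (axes[1], "voxel_volume_mm3", "voxel volume (mm^3)"),
    ):
        for fs, block in per_db.groupby("field_strength_t"):
            ax.scatter(block["scan_time_s"], block[response],
                       marker=markers.get(fs, "s"), label=f"{fs:g}T")
        x = per_db["scan_time_s"].to_numpy()
        y = per_db[response].to_numpy()
        if np.ptp(x) > 0:
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, a + b * xs, "k--", lw=1)
        ax.set_xlabel("scan time (s)")
        ax.set_ylabel(label)
        ax.legend()
    fig.suptitle("scan-time trade-offs (synthetic phantoms)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def plot_age_groups(age_summary: pd.DataFrame, path: str | Path) -> Path:
    """Grouped mean +/- SEM by age bin, per contrast and quantity."""
    order = ["young", "middle", "elderly"]
    quantities = age_summary["quantity"].unique()
    contrasts = age_summary["contrast"].unique()
    fig, axes = plt.subplots(
        len(contrasts), len(quantities),
        figsize=(3.2 * len(quantities), 3.0 * len(contrasts)), squeeze=False,
    )
    for i, contrast in enumerate(contrasts):
        for j, quantity in enumerate(quantities):
            ax = axes[i][j]
            block = (
                age_summary[(age_summary["contrast"] == contrast) & (age_summary["quantity"] == quantity)]
                .set_index("age_group").reindex(order)
            )
            ax.bar(order, block["mean"], yerr=block["sem"], color="lightgrey",
                   edgecolor="black", capsize=3)
            ax.set_title(f"{contrast} {quantity}")
    fig.suptitle("age-group summaries (synthetic phantoms)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
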