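"""Summary figures for cohort reports (file output only, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import AGE_BINS, AGE_LABELS, log_mac


def save_summary_plots(merged: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """FRS histogram, elevated/normal boxplots by age band and sex, and the
    FRS-vs-log-MAC scatter. Expects columns frs, truth_mac_mean,
    truth_elevated, age, sex."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(merged["frs"].dropna(), bins=np.arange(-5.5, 30.5), color="steelblue")
    ax.set_xlabel("Framingham points")
    ax.set_ylabel("participants")
    fig.tight_layout()
    p = out / "frs_histogram.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    band = pd.cut(merged["age"], AGE_BINS, labels=AGE_LABELS, right=False)
    for ax, sex in zip(axes, ("female", "male")):
        sub = merged[merged["sex"] == sex]
        groups = [sub.loc[band[sub.index] == b, "frs"].dropna() for b in AGE_LABELS]
        ax.boxplot(groups, tick_labels=AGE_LABELS)
        ax.set_title(sex)
        ax.set_xlabel("age band")
    axes[0].set_ylabel("Framingham points")
    fig.tight_layout()
    p = out / "frs_by_age_sex.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    x = log_mac(merged["truth_mac_mean"].to_numpy())
    colors = np.where(merged["truth_elevated"], "crimson", "gray")
    ax.scatter(x, merged["frs"], s=8, c=colors, alpha=0.5)
    ax.set_xlabel("log(MAC % + 0.01)")
    ax.set_ylabel("Framingham points")
    fig.tight_layout()
    p = out / "frs_vs_log_mac.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
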