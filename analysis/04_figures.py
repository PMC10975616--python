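#!/usr/bin/env python
"""Basic figures from the aggregate tables: mean speed and |rotation|
profiles against distance to crossing, and maximum rotation vs R = w/s with
the fitted exponential."""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
TABLES = ROOT / "results" / "tables"
FIGS = ROOT / "results" / "figures"


def profiles(kind: str, ylabel: str) -> None:
    df = pd.read_csv(TABLES / f"{kind}.csv")
    angles = sorted(df["angle_deg"].unique())
    fig, axes = plt.subplots(1, len(angles), figsize=(3 * len(angles), 3),
                             sharey=True)
    for ax, angle in zip(np.atleast_1d(axes), angles):
        sub = df[df["angle_deg"] == angle]
        for motivation, grp in sub.groupby("motivation"):
            ls = "-" if motivation == "hurried" else ":"
            ax.plot(grp["d_bin_center"], grp["mean"], ls, label=motivation)
        ax.invert_xaxis()
        ax.set_title(f"{angle:+.0f} deg")
        ax.set_xlabel("distance to crossing [m]")
    np.atleast_1d(axes)[0].set_ylabel(ylabel)
    np.atleast_1d(axes)[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(FIGS / f"{kind}.png", dpi=150)
    plt.close(fig)


def amplitude_fit() -> None:
    runs = pd.read_csv(ROOT / "results" / "run_results.csv")
    fits = pd.read_csv(TABLES / "rotation_fits.csv")
    fig, ax = plt.subplots(figsize=(5, 4))
    ok = runs["max_amplitude"].notna()
    colors = {"normal": "tab:green", "hurried": "tab:blue"}
    for motivation, grp in runs[ok].groupby("motivation"):
        ax.plot(grp["ratio_R"], grp["max_amplitude"].abs(), ".",
                ms=3, alpha=0.4, color=colors[motivation], label=motivation)
    x = np.linspace(0.8, 2.6, 200)
    for _, row in fits.iterrows():
        y = row["a"] * np.exp(-row["b"] * x) + row["d"]
        ax.plot(x, y, "-" if row["motivation"] == "hurried" else "--",
                lw=0.8, color=colors[row["motivation"]], alpha=0.6)
    ax.set_xlabel("R = w/s")
    ax.set_ylabel("|max rotation| [deg]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIGS / "max_rotation_vs_R.png", dpi=150)
    plt.close(fig)


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    profiles("speed_profiles", "speed [m/s]")
    profiles("rotation_profiles", "|rotation| [deg]")
    if (TABLES / "rotation_fits.csv").exists():
        amplitude_fit()
    print(f"figures: {FIGS}")


if __name__ == "__main__":
    main()
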