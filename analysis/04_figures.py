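#!/usr/bin/env python
"""Figures from the analysis tables written by scripts 01-03.

Three panels mirror the study's main displays: the spread of log(rho)
across stressor richness (pairs), mean SCV across richness (four
species), and the community metrics across richness for free vs fixed
total stressor intensity. Reads the CSVs under results/ and writes PNGs
next to them.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_rho(df: pd.DataFrame, path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=False)
    for ax, mode, title in zip(axes, ("unfixed", "fixed"),
                               ("(a) intensity unfixed", "(b) intensity fixed at 90%")):
        sub = df[df.tsi_mode == mode]
        ax.fill_between(sub.s, sub.q10_log_rho, sub.q90_log_rho, alpha=0.3)
        ax.plot(sub.s, sub.mean_log_rho, "o-", ms=3)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xlabel("stressor richness s")
        ax.set_title(title, fontsize=10)
    axes[0].set_ylabel("log ρ (10th-90th pct)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def plot_scv(df: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    for lvl in ("unfixed", "10%", "50%", "90%"):
        sub = df[df.tsi_level == lvl]
        ax.plot(sub.stressor_richness, sub.scv_mean, "o-", ms=3,
                label=f"TSI {lvl}")
    ax.set_xlabel("stressor richness s")
    ax.set_ylabel("mean SCV")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def plot_metrics(agg: pd.DataFrame, path: Path) -> None:
    metricsets = [("function_ratio", "function Yo/Yop"),
                  ("persistence_fraction", "persistence"),
                  ("bray_curtis", "compositional resistance"),
                  ("scaled_complementarity", "C / ΔY"),
                  ("scaled_selection", "S / ΔY")]
    models_present = sorted(agg.model.unique())
    fig, axes = plt.subplots(len(metricsets), 2,
                             figsize=(8, 2.2 * len(metricsets)),
                             sharex=True)
    for row, (metric, label) in enumerate(metricsets):
        for col, tsi in enumerate(("unfixed", "90%")):
            ax = axes[row, col]
            for model in models_present:
                sub = agg[(agg.tsi_level == tsi) & (agg.model == model)] \
                    .sort_values("stressor_richness")
                # for skewed metrics the mean can sit outside the band;
                # clip the whiskers at zero length
                lo = (sub[f"{metric}_mean"] - sub[f"{metric}_q10"]).clip(lower=0)
                hi = (sub[f"{metric}_q90"] - sub[f"{metric}_mean"]).clip(lower=0)
                ax.errorbar(sub.stressor_richness, sub[f"{metric}_mean"],
                            yerr=[lo, hi], fmt="o-", ms=3, capsize=2,
                            label=model)
            if row == 0:
                ax.set_title(f"TSI {tsi}", fontsize=10)
            if col == 0:
                ax.set_ylabel(label, fontsize=9)
    axes[-1, 0].set_xlabel("stressor richness s")
    axes[-1, 1].set_xlabel("stressor richness s")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    r = args.results
    made = []
    if (r / "rho_summary.csv").exists():
        plot_rho(pd.read_csv(r / "rho_summary.csv"), r / "rho_summary.png")
        made.append("rho_summary.png")
    if (r / "scv_summary.csv").exists():
        plot_scv(pd.read_csv(r / "scv_summary.csv"), r / "scv_summary.png")
        made.append("scv_summary.png")
    if (r / "factorial_aggregate.csv").exists():
        plot_metrics(pd.read_csv(r / "factorial_aggregate.csv"),
                     r / "community_metrics.png")
        made.append("community_metrics.png")
    if not made:
        print(f"no analysis tables found under {r}; run scripts 01-03 first")
    else:
        print("wrote " + ", ".join(str(r / m) for m in made))


if __name__ == "__main__":
    main()
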