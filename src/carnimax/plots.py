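"""Optional matplotlib figures for model evaluation and prediction."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

__all__ = ["plot_gof", "plot_cwres", "plot_vpc", "plot_efficacy"]


def plot_gof(pred_table, path) -> None:
    """Individual predictions vs observations with the identity line."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pred_table["individual_pred"], pred_table["observation"], s=25)
    lims = [
        min(pred_table["individual_pred"].min(), pred_table["observation"].min()),
        max(pred_table["individual_pred"].max(), pred_table["observation"].max()),
    ]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("individual prediction (%)")
    ax.set_ylabel("observation (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cwres(times, residuals, path) -> None:
    """CWRES vs time and a normal QQ panel."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 4))
    ax1.scatter(times, residuals, s=25)
    ax1.axhline(0.0, color="k", lw=1)
    for y in (-2, 2):
        ax1.axhline(y, color="grey", ls="--", lw=0.8)
    ax1.set_xlabel("time (weeks)")
    ax1.set_ylabel("CWRES")
    stats.probplot(np.asarray(residuals), dist="norm", plot=ax2)
    ax2.set_title("")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vpc(vpc, path) -> None:
    """Prediction-corrected VPC: simulated bands and corrected observations."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.fill_between(vpc.bins, vpc.sim_p2_5, vpc.sim_p97_5, alpha=0.25, label="95% band")
    ax.plot(vpc.bins, vpc.sim_p50, lw=1.5, label="simulated median")
    for b, obs in zip(vpc.bins, vpc.observed):
        ax.scatter(np.full(len(obs), b), obs, color="k", s=20, zorder=3)
    ax.set_xlabel("time (weeks)")
    ax.set_ylabel("prediction-corrected effect (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_efficacy(bands, milestones, path) -> None:
    """Simulated efficacy bands with milestone markers."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.fill_between(bands.times_weeks, bands.lower, bands.upper, alpha=0.25)
    ax.plot(bands.times_weeks, bands.median, lw=1.5)
    for f, t in zip(milestones.fractions, milestones.times_weeks):
        ax.axvline(t, color="grey", ls="--", lw=0.8)
        ax.text(t, ax.get_ylim()[1], f"{f:.0%}", ha="center", va="bottom", fontsize=8)
    ax.set_xlabel("time (weeks)")
    ax.set_ylabel("effect (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
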