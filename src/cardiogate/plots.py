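"""Report figures: cumulative onset curves and condition-mean bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_cumulative_onsets", "plot_condition_means"]


def plot_cumulative_onsets(hist, path) -> None:
    """Cumulative onset-latency curves per intended-phase condition,
    with the recoding windows shaded."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for phase, grp in hist.groupby("intended_phase"):
        ax.step(grp["bin_ms"], grp["cum_freq"], where="post", label=phase)
    ax.axvspan(200, 400, alpha=0.12, color="tab:red", label="systole window")
    ax.axvspan(450, 800, alpha=0.12, color="tab:blue", label="diastole window")
    ax.set_xlabel("stimulus onset relative to R-wave (ms)")
    ax.set_ylabel("cumulative frequency")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_condition_means(cell_means, path) -> None:
    """Mean accuracy (+/- SEM) per prime x object x phase cell."""
    fig, ax = plt.subplots(figsize=(7, 4))
    cm = cell_means.copy()
    cm["label"] = cm["prime"] + "\n" + cm["object"] + "\n" + cm["phase"]
    ax.bar(cm["label"], cm["mean"], yerr=cm["sem"], capsize=3)
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1)
    ax.tick_params(axis="x", labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
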