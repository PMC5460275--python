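"""Basic plots for pipeline reports (accuracy curves, scatter diagnostics)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_accuracy_curves(curves, path, title="Prediction accuracy vs marker count"):
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.errorbar(
            curve.marker_counts,
            curve.mean_accuracy,
            yerr=curve.sd_accuracy,
            label=f"{curve.trait} ({curve.strategy})",
            capsize=2,
        )
    ax.set_xlabel("markers")
    ax.set_ylabel("prediction accuracy")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_h2_pairs(estimates, path):
    """Full-set vs subset genomic heritability per trait."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    x = [e.h2_full for e in estimates]
    y = [e.h2_subset for e in estimates]
    ax.scatter(x, y)
    for e in estimates:
        ax.annotate(e.trait, (e.h2_full, e.h2_subset), fontsize=7)
    lim = [0, 1]
    ax.plot(lim, lim, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("h2 (full marker set)")
    ax.set_ylabel("h2 (association subset)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_pred_obs(gebv_table, path, trait="trait"):
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(gebv_table["predicted"], gebv_table["observed"], s=8, alpha=0.6)
    ax.set_xlabel("predicted (GEBV)")
    ax.set_ylabel("observed")
    ax.set_title(trait)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
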