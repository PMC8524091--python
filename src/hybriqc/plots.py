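"""Static QC plots (matplotlib, Agg backend). Optional outputs of the CLI."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def efficiency_bars(efficiency: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of per-marker efficiency (percent of pairs distinguished)."""
    fig, ax = plt.subplots(figsize=(8, 4))
    sub = efficiency[efficiency["defined"]]
    ax.bar(sub["marker_id"], sub["percent_efficiency"], color="#4878a8")
    ax.set_ylabel("marker efficiency (%)")
    ax.set_ylim(0, 100)
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def heterozygosity_box(per_sample: pd.DataFrame, path: str | Path) -> None:
    """Box plot of per-sample heterozygosity, parents vs F1s."""
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = [g for g in ("parent", "F1") if (per_sample["group"] == g).any()]
    data = [per_sample.loc[per_sample["group"] == g, "pr_het"].dropna()
            for g in groups]
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel("proportion of heterozygous loci")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def success_histogram(cross_success: pd.DataFrame, path: str | Path) -> None:
    """Histogram of per-cross hybridity success rates."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(cross_success["success_rate"].dropna(), bins=10, range=(0, 100),
            color="#6aa84f", edgecolor="white")
    ax.set_xlabel("hybridity success rate (%)")
    ax.set_ylabel("number of crosses")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pca_scatter(scores: pd.DataFrame, groups: pd.Series,
                path: str | Path) -> None:
    """PC1 vs PC2 scatter, colored by sample group (parent / F1)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for group, color in (("parent", "#c0504d"), ("F1", "#4878a8"),
                         ("unassigned", "#999999")):
        idx = groups[groups == group].index
        idx = [s for s in idx if s in scores.index]
        if not idx:
            continue
        ax.scatter(scores.loc[idx, "PC1"], scores.loc[idx, "PC2"], s=12,
                   alpha=0.6, label=group, color=color)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
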