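"""Figure-data exports: per-gene delta bar charts by group."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_delta_bars(delta: pd.DataFrame, path: str | Path, title: str = "DG vs CA log ratios"):
    """Bar chart of per-gene delta values, group A then group B.

    Positive bars indicate DG enrichment, negative bars CA enrichment.
    """
    df = delta[delta["group"].isin(["A", "B"])].copy()
    df = df.sort_values(["group", "delta"], ascending=[True, False]).reset_index(drop=True)
    colors = df["group"].map({"A": "#c0392b", "B": "#2471a3"})
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(df)), 4))
    ax.bar(range(len(df)), df["delta"], color=colors)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df["gene"], rotation=90, fontsize=7)
    ax.set_ylabel(r"$\Delta$ = log10(DG + c) - log10(meanCA + c)")
    ax.set_title(title)
    handles = [plt.Rectangle((0, 0), 1, 1, color="#c0392b"),
               plt.Rectangle((0, 0), 1, 1, color="#2471a3")]
    ax.legend(handles, ["group A (challenge)", "group B (sufficiency)"], frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


__all__ = ["plot_delta_bars"]
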