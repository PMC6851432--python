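"""CSV and figure reports for per-residue comparisons."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["comparison_figure", "save_comparison_figure"]


def _marker_rows(frame: pd.DataFrame, flip_col: str, twist_col: str):
    flips = frame.index[frame[flip_col].fillna(False).astype(bool)]
    twists = frame.index[frame[twist_col].fillna(False).astype(bool)]
    return flips, twists


def comparison_figure(frame: pd.DataFrame, title: str = ""):
    """Multi-panel per-residue comparison chart.

    Panels: model backbone score trace; model - template backbone
    difference (negative = model improved); sidechain trace; sidechain
    difference.  CA residual distances shade the background; peptide
    bond problems (cis/trans flips, twists) are marked with crosses and
    triangles.
    """
    x = np.arange(len(frame))
    fig, axes = plt.subplots(4, 1, figsize=(10, 9), sharex=True)

    def shade(ax):
        for col, color in (("template_ca_residual", "tab:green"),
                           ("model_ca_residual", "tab:purple")):
            if col in frame:
                vals = frame[col].to_numpy(dtype=float)
                finite = np.isfinite(vals)
                if finite.any() and np.nanmax(vals) > 0:
                    alpha = 0.25 * np.clip(vals / max(np.nanmax(vals), 1e-9), 0, 1)
                    for xi, a in zip(x[finite], alpha[finite]):
                        ax.axvspan(xi - 0.5, xi + 0.5, color=color,
                                   alpha=float(a), lw=0)

    ax = axes[0]
    shade(ax)
    ax.plot(x, frame["model_backbone"], color="tab:purple", lw=1,
            label="model")
    if "template_backbone" in frame:
        ax.plot(x, frame["template_backbone"], color="tab:green", lw=1,
                label="template")
    flips, twists = _marker_rows(frame, "model_omega_flip", "model_omega_twist")
    ax.plot(x[flips], np.ones(len(flips)) * 1.02, "x", color="red",
            label="cis/trans flip")
    ax.plot(x[twists], np.ones(len(twists)) * 1.06, "v", color="darkorange",
            label="twisted peptide")
    ax.set_ylabel("backbone score")
    ax.legend(loc="upper right", fontsize=7)

    ax = axes[1]
    ax.axhline(0, color="0.6", lw=0.8)
    ax.bar(x, frame["d_backbone"].fillna(0), color="0.3", width=0.9)
    ax.set_ylabel("Δ backbone\n(model − template)")

    ax = axes[2]
    shade(ax)
    ax.plot(x, frame["model_sidechain"], color="tab:purple", lw=1)
    if "template_sidechain" in frame:
        ax.plot(x, frame["template_sidechain"], color="tab:green", lw=1)
    ax.set_ylabel("sidechain score")

    ax = axes[3]
    ax.axhline(0, color="0.6", lw=0.8)
    ax.bar(x, frame["d_sidechain"].fillna(0), color="0.3", width=0.9)
    ax.set_ylabel("Δ sidechain")
    ax.set_xlabel("residue")
    if len(frame):
        ticks = x[:: max(1, len(x) // 20)]
        ax.set_xticks(ticks)
        ax.set_xticklabels(frame["seq"].iloc[ticks], fontsize=7)

    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def save_comparison_figure(frame: pd.DataFrame, path, title: str = "") -> None:
    fig = comparison_figure(frame, title=title)
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
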