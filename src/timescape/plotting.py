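"""Minimal plotting helpers: log-HR heatmaps and Kaplan-Meier curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["loghr_heatmap", "km_plot"]


def loghr_heatmap(scan: pd.DataFrame, path, value_col: str = "log_HR") -> None:
    """Heatmap of a tidy survival scan (feature rows annotated with tiers)."""
    sub = scan[scan["skip_reason"] == ""] if "skip_reason" in scan.columns else scan
    vals = sub[value_col].to_numpy()[:, None]
    fig, ax = plt.subplots(figsize=(4, 0.4 * len(sub) + 1))
    vmax = np.nanmax(np.abs(vals)) or 1.0
    im = ax.imshow(vals, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(len(sub)))
    ax.set_yticklabels(
        [f"{f} {t}" for f, t in zip(sub["feature"], sub.get("tier", [""] * len(sub)))]
    )
    ax.set_xticks([])
    fig.colorbar(im, ax=ax, label="log-HR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_plot(estimates: dict, path) -> None:
    """Overlayed Kaplan-Meier step curves with confidence bands.

    ``estimates`` maps a label (e.g. a stage) to a KMEstimate.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, est in estimates.items():
        ax.step(est.times, est.survival, where="post", label=str(label))
        ax.fill_between(est.times, est.ci_lower, est.ci_upper,
                        step="post", alpha=0.2)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
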