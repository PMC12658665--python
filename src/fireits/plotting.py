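"""Point-and-whisker plots of daily percent excess estimates."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .excess import ExcessEstimate


def plot_excess_profile(
    daily: Sequence[ExcessEstimate],
    cumulative: ExcessEstimate | None = None,
    title: str = "",
    path=None,
):
    """Daily percent excess point estimates with 95% empirical CI whiskers."""
    dates = [pd.Timestamp(e.window[0]) for e in daily]
    pts = [e.pct_excess for e in daily]
    lo = [e.pct_excess - e.ci_low for e in daily]
    hi = [e.ci_high - e.pct_excess for e in daily]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.errorbar(dates, pts, yerr=[lo, hi], fmt="o", capsize=3, color="tab:red")
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_ylabel("% excess visits")
    label = title
    if cumulative is not None:
        label += (
            f"  (week: {cumulative.pct_excess:.0f}%"
            f" [{cumulative.ci_low:.0f}%, {cumulative.ci_high:.0f}%])"
        )
    ax.set_title(label)
    fig.autofmt_xdate()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
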