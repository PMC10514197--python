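"""Optional plots: service-accumulation and targets-met curves."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_accumulation(accumulation: pd.DataFrame, path: Optional[str | Path] = None):
    """Percent of each service captured (and targets met) vs budget fraction."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = accumulation["budget_fraction"] * 100
    for col in accumulation.columns:
        if col.endswith("_percent"):
            ax.plot(x, accumulation[col], label=col[: -len("_percent")])
    if "percent_targets_met" in accumulation:
        ax.plot(x, accumulation["percent_targets_met"], "k--", label="targets met")
    ax.set_xlabel("area budget (% of mangrove extent)")
    ax.set_ylabel("% captured")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
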