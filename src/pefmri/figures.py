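"""Optional bar-chart summaries of extracted contrast values."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def cope_bar_chart(records: pd.DataFrame, path) -> None:
    """Group x session mean +/- SEM bars for one ROI x contrast table."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    sessions = list(pd.unique(records["session"]))
    width = 0.35
    xs = np.arange(len(sessions))
    for off, (group, part) in zip((-width / 2, width / 2), records.groupby("group")):
        means = [part[part.session == s]["value"].mean() for s in sessions]
        sems = [
            part[part.session == s]["value"].sem() for s in sessions
        ]
        ax.bar(xs + off, means, width, yerr=sems, capsize=3, label=group)
    ax.set_xticks(xs, sessions)
    ax.set_ylabel("mean COPE (a.u.)")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
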