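"""Plot helpers: Kaplan-Meier curves and cognitive trajectories."""

from __future__ import annotations

import pandas as pd


def plot_kaplan_meier(curves: dict[str, pd.DataFrame], ax=None):
    """Step plot of per-group product-limit survival curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, sf in curves.items():
        ax.step(sf["time"], sf["survival"], where="post", label=name)
    ax.set_xlabel("months from baseline")
    ax.set_ylabel("progression-free proportion")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    return ax


def plot_trajectories(visits: pd.DataFrame, cohort: pd.DataFrame, domain: str,
                      group: str = "subtype", ax=None):
    """Group-mean score per visit month with +-1 SE ribbons."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    df = visits.merge(cohort[["subject_id", group]], on="subject_id")
    for name, sub in df.groupby(group):
        agg = sub.groupby("month")[domain].agg(["mean", "sem"])
        ax.plot(agg.index, agg["mean"], label=name)
        ax.fill_between(agg.index, agg["mean"] - agg["sem"], agg["mean"] + agg["sem"],
                        alpha=0.2)
    ax.set_xlabel("months from baseline")
    ax.set_ylabel(f"{domain} composite")
    ax.legend(frameon=False)
    return ax
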