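"""Plot helpers (matplotlib is imported lazily)."""

from __future__ import annotations

import numpy as np

from .engine import STATES, CohortTrace


def plot_trace(trace: CohortTrace, ax=None):
    """Stacked state-occupancy plot over the model horizon."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = trace.df["time_years"]
    occ = np.vstack([trace.df[f"occ_{s}"] for s in STATES])
    ax.stackplot(t, occ, labels=STATES)
    ax.set_xlabel("years")
    ax.set_ylabel("state occupancy")
    ax.set_ylim(0, 1)
    ax.legend(loc="center left", fontsize="small")
    return ax


def plot_tornado(dsa_table, ax=None):
    """Horizontal tornado diagram from a one-way DSA table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = dsa_table.iloc[::-1]
    base = df["base_result"].iloc[0]
    y = np.arange(len(df))
    ax.barh(y, df["high_result"] - base, left=base, color="tab:orange", label="high")
    ax.barh(y, df["low_result"] - base, left=base, color="tab:blue", label="low")
    ax.axvline(base, color="k", lw=0.8)
    ax.set_yticks(y, df["parameter"])
    ax.legend(fontsize="small")
    return ax
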