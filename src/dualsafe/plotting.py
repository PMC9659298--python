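"""Trajectory plots: sawtooth stock panel and the SB time series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless; plots are files, never windows
import matplotlib.pyplot as plt

__all__ = ["plot_trajectory"]


def plot_trajectory(traj, which: str = "stocks", path=None):
    """Plot a simulated trajectory.

    ``which='stocks'`` draws the three implicit stocks (the intervention
    sawtooth); ``which='SB'`` draws the daily safety-behavior series with
    intervention days marked. Returns the matplotlib Figure; if ``path``
    is given the figure is also written there (PNG/SVG by extension).
    """
    if len(traj) == 0:
        raise ValueError("cannot plot an empty trajectory")
    if which not in ("stocks", "SB"):
        raise ValueError(f"which must be 'stocks' or 'SB', got {which!r}")

    t = traj.t
    fig, ax = plt.subplots(figsize=(9, 4))
    if which == "stocks":
        for j, (name, color) in enumerate(
            [("SCA", "tab:blue"), ("SCO", "tab:orange"), ("SM", "tab:green")]
        ):
            ax.plot(t, traj.stocks[:, j], label=name, color=color, lw=1.2)
        ax.set_ylabel("implicit stock level (dimensionless)")
        ax.set_ylim(bottom=0)
    else:
        ax.plot(t, traj.SB, lw=0.8, color="tab:blue", label="SB")
        ax.axhline(0.0, color="grey", lw=0.6)
        ax.set_ylabel("safety behavior SB (dimensionless)")
    for day in traj.intervention_days():
        ax.axvline(day, color="lightgrey", lw=0.5, zorder=0)
    ax.set_xlabel("time (days)")
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
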