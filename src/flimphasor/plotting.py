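"""Phasor-plot export: measurement scatter, universal-circle overlay, and
standard deviational ellipses, with the plotted data dumped to CSV."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .flim_data import MeasurementPoint
from .phasor import universal_circle
from .stats import std_dev_ellipse

__all__ = ["phasor_plot"]


def phasor_plot(
    measurements: list[MeasurementPoint],
    harmonic: int = 1,
    path: str | Path | None = None,
    csv_path: str | Path | None = None,
):
    """Scatter the per-measurement phasors by condition, with ellipses."""
    records = [
        {"condition": m.condition, "g": m.phasors[harmonic][0], "s": m.phasors[harmonic][1]}
        for m in measurements
    ]
    df = pd.DataFrame(records)
    if csv_path is not None:
        df.to_csv(csv_path, index=False, float_format="%.12g")

    fig, ax = plt.subplots(figsize=(5, 3.2))
    circle = universal_circle(200)
    ax.plot(circle[:, 0], circle[:, 1], color="0.6", lw=1)
    for cond, grp in df.groupby("condition"):
        pts = grp[["g", "s"]].to_numpy()
        sc = ax.scatter(pts[:, 0], pts[:, 1], s=12, label=cond)
        if len(pts) >= 3:
            try:
                boundary = std_dev_ellipse(pts).boundary(120)
                ax.plot(boundary[:, 0], boundary[:, 1], lw=1,
                        color=sc.get_facecolor()[0])
            except ValueError:
                pass
    ax.set_xlabel(f"g (harmonic {harmonic})")
    ax.set_ylabel(f"s (harmonic {harmonic})")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 0.65)
    ax.legend(fontsize=6, loc="upper right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
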