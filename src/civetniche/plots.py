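"""Diel activity figures (two kernel densities with the shared-minimum area)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .temporal_overlap import CircularSample, circular_kde


def activity_overlap_plot(
    s1: CircularSample,
    s2: CircularSample,
    path: str | Path,
    labels: tuple[str, str] | None = None,
) -> None:
    """Plot both activity densities over the 24-h clock and shade min(f, g).

    The x axis is in hours; densities are rescaled per-hour so the shaded
    area is the overlap coefficient Δ1.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = circular_kde(s1, adjust=0.8)
    g = circular_kde(s2, adjust=0.8)
    hours = f.grid / (2 * np.pi) * 24.0
    scale = 2 * np.pi / 24.0  # per-radian -> per-hour
    fv, gv = f.values * scale, g.values * scale
    labels = labels or (s1.species or "species 1", s2.species or "species 2")

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(hours, fv, label=f"{labels[0]} (n={s1.n})")
    ax.plot(hours, gv, "--", label=f"{labels[1]} (n={s2.n})")
    ax.fill_between(hours, np.minimum(fv, gv), color="grey", alpha=0.4, label="overlap")
    ax.set_xlim(0, 24)
    ax.set_xticks(range(0, 25, 4))
    ax.set_xlabel("Time of day (h)")
    ax.set_ylabel("Activity density (h$^{-1}$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
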