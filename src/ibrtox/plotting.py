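"""Radar (star) chart for IBR results.

One polygon per group on equally spaced biomarker axes, radial length S,
with a dashed zero-reference line marking where the direction-aligned score
Z crosses 0 on each axis.  SVG output is byte-deterministic so pipeline
checksums reproduce.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ibr import IBRResult

__all__ = ["radar_chart"]

# stable ids + no timestamp -> identical SVG bytes across runs
matplotlib.rcParams["svg.hashsalt"] = "ibrtox"


def radar_chart(result: IBRResult, path: str | Path | None = None,
                title: str = "Integrated biomarker response"):
    """Draw the IBR star plot; write deterministic SVG when ``path`` given.

    Axis i sits at angle 2*pi*i/k; each group's polygon has vertices at
    radius S.  The dashed line is the Z = 0 reference: per biomarker it
    lies at radius |min(Z)| (the translation shift), the baseline above
    which a group responded more than the least-responsive group.
    """
    S = result.S.to_numpy()
    groups = list(result.S.index)
    biomarkers = list(result.S.columns)
    k = len(biomarkers)
    angles = np.array([2.0 * math.pi * i / k for i in range(k)])
    closed = np.concatenate([angles, angles[:1]])

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for i, g in enumerate(groups):
        radii = np.concatenate([S[i, :], S[i, :1]])
        ax.plot(closed, radii, linewidth=1.5,
                label=f"{g} (IBR = {result.ibr_index[g]:.3f})")
        ax.fill(closed, radii, alpha=0.15)
    zero_ref = np.abs(result.Z.to_numpy().min(axis=0))
    ax.plot(closed, np.concatenate([zero_ref, zero_ref[:1]]),
            linestyle="--", color="black", linewidth=1.0, label="0-axis reference")
    ax.set_xticks(angles)
    ax.set_xticklabels(biomarkers, fontsize=8)
    ax.set_title(title)
    ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), format="svg", metadata={"Date": None})
        plt.close(fig)
        return None
    return fig
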