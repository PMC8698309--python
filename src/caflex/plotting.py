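"""Minimal plot helpers (RMSF profile, DCCM heat map, PC scatter).

Each helper returns a matplotlib Figure; styling is deliberately plain.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .trajectory import CORR_BAND, RMSF_HIGH_NM, CorrelationMatrix


def plot_rmsf(rmsf_nm, residue_numbers=None, threshold: float = RMSF_HIGH_NM):
    fig, ax = plt.subplots(figsize=(7, 3))
    x = residue_numbers if residue_numbers is not None else np.arange(1, len(rmsf_nm) + 1)
    ax.plot(x, rmsf_nm, lw=1)
    ax.axhline(threshold, color="red", lw=0.8, ls="--")
    ax.set_xlabel("residue")
    ax.set_ylabel("RMSF (nm)")
    fig.tight_layout()
    return fig


def plot_dccm(C: CorrelationMatrix, band: float = CORR_BAND):
    fig, ax = plt.subplots(figsize=(5, 4.5))
    # three-band colouring: anticorrelated / neutral / correlated
    cmap = matplotlib.colors.ListedColormap(["deeppink", "white", "cyan"])
    bounds = [-1.0, -band, band, 1.0]
    norm = matplotlib.colors.BoundaryNorm(bounds, cmap.N)
    im = ax.imshow(C.matrix, cmap=cmap, norm=norm, origin="lower")
    fig.colorbar(im, ax=ax, ticks=bounds, label="C_ij")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    fig.tight_layout()
    return fig


def plot_pc_scatter(projections, labels=None, dims=(0, 1)):
    fig, ax = plt.subplots(figsize=(4.5, 4))
    a, b = dims
    c = labels if labels is not None else np.arange(len(projections))
    sc = ax.scatter(projections[:, a], projections[:, b], c=c, s=12, cmap="viridis")
    fig.colorbar(sc, ax=ax)
    ax.set_xlabel(f"PC{a + 1} (A)")
    ax.set_ylabel(f"PC{b + 1} (A)")
    fig.tight_layout()
    return fig
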