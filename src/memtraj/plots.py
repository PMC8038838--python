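"""Best-effort plotting hooks for the pipeline outputs."""

from __future__ import annotations

import numpy as np
import pandas as pd

#: display bands for ligand-proximity colouring: low band in purple-blue,
#: high band in pink
PROXIMITY_BANDS = (((0.01, 0.3), "#6a5acd"), ((0.4, 1.0), "#ff69b4"))


def plot_proximity(df: pd.DataFrame, ax=None, color_bands: bool = False):
    """Proximity vs residue line plot; one call per group table.

    With ``color_bands`` residues falling in the low/high display bands
    are marked in the conventional purple-blue/pink colours.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(df["residue_seq"], df["proximity"], lw=1, color="0.2")
    if color_bands:
        for (lo, hi), color in PROXIMITY_BANDS:
            sel = (df["proximity"] >= lo) & (df["proximity"] <= hi)
            ax.scatter(
                df.loc[sel, "residue_seq"],
                df.loc[sel, "proximity"],
                s=12,
                color=color,
                zorder=3,
            )
    ax.set_xlabel("residue")
    ax.set_ylabel("proximity")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_helicity(df: pd.DataFrame, threshold: float = 0.35, ax=None):
    """Helicity profile with the hydrogen-bond threshold line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(df["residue_seq"], df["mean_distance_nm"], lw=1, color="0.2")
    ax.axhline(threshold, color="tab:blue", lw=1)
    ax.set_xlabel("residue")
    ax.set_ylabel("O(n)···N(n+4) distance (nm)")
    return ax


def plot_channel_profile(profile, ax=None):
    """Radius vs z for one channel profile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(profile.radius, profile.z, lw=1.5)
    ax.set_xlabel("pore radius (nm)")
    ax.set_ylabel("z (nm)")
    return ax
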