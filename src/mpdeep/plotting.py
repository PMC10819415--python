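"""Plotting helpers for SBR maps and profiles (matplotlib)."""

from __future__ import annotations

import numpy as np

from .sbr import SBRMap
from .stacks import SBRProfile

__all__ = ["plot_sbr_map", "plot_sbr_profile"]


def plot_sbr_map(sbr_map: SBRMap, ax=None, cmap: str = "viridis"):
    """Iso-ratio contour map of SBR versus imaging depth and scattering length.

    Contours are drawn at the map's export levels (20 … 1/100) on a log
    colour scale; depth on the x axis, scattering length on the y axis.
    """
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ratio = np.where(np.isfinite(sbr_map.ratio), sbr_map.ratio, np.nan)
    levels = sorted(sbr_map.contour_levels)
    mesh = ax.pcolormesh(
        sbr_map.depths_um,
        sbr_map.scattering_lengths_um,
        ratio,
        norm=LogNorm(vmin=min(levels), vmax=max(levels)),
        cmap=cmap,
        shading="nearest",
    )
    cs = ax.contour(
        sbr_map.depths_um,
        sbr_map.scattering_lengths_um,
        ratio,
        levels=levels,
        colors="white",
        linewidths=0.8,
    )
    ax.clabel(cs, fmt=lambda v: f"{v:g}" if v >= 1 else f"1/{round(1 / v):d}", fontsize=7)
    ax.figure.colorbar(mesh, ax=ax, label="signal-to-background ratio")
    ax.set_xlabel("imaging depth (µm)")
    ax.set_ylabel("scattering length (µm)")
    ax.set_title(f"{sbr_map.order}-photon excitation")
    return ax


def plot_sbr_profile(profile: SBRProfile, ax=None):
    """Signal, background and SBR versus depth for one analysed stack."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.semilogy(profile.depths_um, profile.signal, "o-", label="signal")
    ax.semilogy(profile.depths_um, profile.background, "s--", label="background")
    ax.semilogy(profile.depths_um, profile.ratio, "^:", label="SBR")
    ax.set_xlabel("depth (µm)")
    ax.set_ylabel("counts above zero-value / ratio")
    ax.legend()
    ax.set_title(f"{profile.channel} channel")
    return ax
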