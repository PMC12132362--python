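"""Thin plotting helpers: scalp topographies, envelopes, BF time courses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .montage import SensorMontage


def _flat_xy(montage: SensorMontage) -> np.ndarray:
    """Azimuthal-equidistant projection of sensor positions (nose up)."""
    p = montage.positions
    theta = np.arccos(np.clip(p[:, 2], -1, 1))
    phi = np.arctan2(p[:, 0], p[:, 1])
    return np.column_stack([theta * np.sin(phi), theta * np.cos(phi)])


def plot_bf_topomap(values: np.ndarray, montage: SensorMontage, title: str = "",
                    path=None, ax=None, cmap: str = "RdBu_r"):
    """Scatter topography of one value per sensor (e.g. window-avg log10BF)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    xy = _flat_xy(montage)
    vmax = float(np.nanmax(np.abs(values))) or 1.0
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, s=60, cmap=cmap,
                    vmin=-vmax, vmax=vmax, edgecolors="k", linewidths=0.3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    plt.colorbar(sc, ax=ax, shrink=0.7, label="log10 BF")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_envelope(times_ms: np.ndarray, envelopes: dict, title: str = "",
                  path=None, ax=None):
    """Envelope time courses; ``envelopes`` maps label -> 1-D array (µV)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    for label, env in envelopes.items():
        ax.plot(times_ms, env, label=label, lw=1.2)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
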