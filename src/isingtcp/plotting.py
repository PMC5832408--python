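"""Plotting helpers for sweep tables, phase diagrams and TCP slice maps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DoseGrid

__all__ = ["plot_dose_response", "plot_phase_diagram", "plot_tcp_slice"]

_PHASE_COLORS = {"uncontrolled": 0.0, "disordered": 0.5, "controlled": 1.0}


def plot_dose_response(sweep: pd.DataFrame, region: str = "all", ax=None):
    """Average TCP versus the sweep control parameter, one curve per lambda."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = sweep[sweep.region == region]
    name = sub.control_name.iloc[0] if len(sub) else "control"
    for lam, grp in sub.groupby("lam_cm"):
        grp = grp.sort_values("control")
        ax.errorbar(grp.control, grp.tcp_avg, yerr=3 * grp.stderr,
                    label=f"$\\lambda$ = {lam:g} cm", marker="o", ms=3, capsize=2)
    ax.set_xlabel(name)
    ax.set_ylabel("TCP$_{avg}$")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def plot_phase_diagram(labels: np.ndarray, delta_d_values, lam_values, ax=None):
    """Heatmap of the uncontrolled / disordered / controlled phases."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    z = np.vectorize(_PHASE_COLORS.get)(labels)
    dd = np.asarray(delta_d_values, dtype=float)
    lam = np.asarray(lam_values, dtype=float)
    mesh = ax.pcolormesh(dd, lam, z, cmap="viridis", vmin=0, vmax=1, shading="nearest")
    ax.set_xlabel("$\\Delta D$ (Gy)")
    ax.set_ylabel("$\\lambda$ (cm)")
    cbar = plt.colorbar(mesh, ax=ax, ticks=[0, 0.5, 1])
    cbar.ax.set_yticklabels(["uncontrolled", "disordered", "controlled"])
    return ax


def plot_tcp_slice(grid: DoseGrid, values: np.ndarray, z_index: int = 0, ax=None, **imshow_kw):
    """Render one axial (constant-z) slice of a per-voxel map on the lattice."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    a = grid.voxel_edge
    idx = np.round(grid.positions / a).astype(int)
    idx -= idx.min(axis=0)
    zs = np.unique(idx[:, 2])
    if z_index not in zs:
        raise ValueError(f"z_index {z_index} not among slice indices {zs.tolist()}")
    sel = idx[:, 2] == z_index
    nx, ny = idx[:, 0].max() + 1, idx[:, 1].max() + 1
    img = np.full((nx, ny), np.nan)
    img[idx[sel, 0], idx[sel, 1]] = values[sel]
    imshow_kw.setdefault("vmin", 0.0)
    imshow_kw.setdefault("vmax", 1.0)
    im = ax.imshow(img.T, origin="lower", **imshow_kw)
    ax.set_xlabel("x (voxels)")
    ax.set_ylabel("y (voxels)")
    plt.colorbar(im, ax=ax)
    return ax
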