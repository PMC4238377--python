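"""Map renderings (PNG).  The numeric layers are the source of truth; these
figures are derived views in the style of the study: neighbor maps coloured
purple-to-red, isodensity grids saturating at a fixed ceiling, and radial
bar profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .topography import DensityGrid, NeighborMap, RadialProfile


def _rainbow(n: int):
    return plt.get_cmap("rainbow")(np.linspace(0, 1, n))


def plot_neighbor_map(nmap: NeighborMap, contour: np.ndarray | None, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = _rainbow(nmap.scale.n_classes)
    df = nmap.cells
    ax.scatter(df["x_mm"], df["y_mm"], c=colors[df["color_bin"]], s=6, linewidths=0)
    if contour is not None:
        ax.plot(*np.vstack([contour, contour[:1]]).T, color="k", lw=0.8)
    ax.set_aspect("equal")
    ax.set_title(f"{nmap.n_cells} cells, r = {nmap.radius} mm")
    ax.set_xlabel("nasal → (mm)")
    ax.set_ylabel("superior → (mm)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_isodensity(grid: DensityGrid, contour: np.ndarray | None, path,
                    n_classes: int = 12) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    side = float(np.sqrt(grid.bin_area))
    colors = _rainbow(n_classes)
    cls = grid.density_class(n_classes)
    for (x0, y0), c in zip(grid.bins[["bin_x", "bin_y"]].to_numpy(), cls):
        ax.add_patch(plt.Rectangle((x0, y0), side, side, color=colors[c], linewidth=0))
    if contour is not None:
        ax.plot(*np.vstack([contour, contour[:1]]).T, color="k", lw=0.8)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_title(f"{grid.total_count} cells, bin = {grid.bin_area:.5f} mm²")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_radial_profile(profile: RadialProfile, path, per_quadrant: bool = True) -> None:
    centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
    width = float(np.diff(profile.bin_edges[:2])[0])
    if per_quadrant:
        fig, axes = plt.subplots(1, 4, figsize=(14, 3), sharey=True)
        for ax, col in zip(axes, profile.per_quadrant.columns):
            ax.bar(centers, profile.per_quadrant[col], width=0.9 * width)
            ax.set_title(col)
            ax.set_xlabel("distance from ON (mm)")
        axes[0].set_ylabel("cells")
    else:
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(centers, profile.total, width=0.9 * width)
        ax.set_xlabel("distance from ON (mm)")
        ax.set_ylabel("cells")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
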