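"""Optional terrain-map rendering (thin layer over TerrainGrid).

The numerical grid is the tested artifact; this module only draws it.
Requires matplotlib (install the ``plot`` extra).
"""

from __future__ import annotations

from .smooths import TerrainGrid


def plot_terrain(grid: TerrainGrid, ax=None, n_isolines: int = 8, cmap: str = "viridis"):
    """Filled-contour terrain map with isolines of predicted dorsum position.

    x axis: skill score; y axis: normalized vowel position; color and red
    isolines: predicted normalized consonant position. Flat (straight)
    isolines mean the skill-by-vowel interaction is linear; curvature
    signals nonlinearity.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.contourf(grid.score_grid, grid.vowel_grid, grid.values.T, levels=30, cmap=cmap)
    cs = ax.contour(grid.score_grid, grid.vowel_grid, grid.values.T,
                    levels=n_isolines, colors="red", linewidths=0.8)
    ax.clabel(cs, fontsize=7, fmt="%.2f")
    ax.set_xlabel(grid.score_name)
    ax.set_ylabel("vowel dorsum position (normalized)")
    ax.set_title(f"/{grid.consonant}/")
    plt.colorbar(mesh, ax=ax, label="predicted consonant dorsum position")
    return ax
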