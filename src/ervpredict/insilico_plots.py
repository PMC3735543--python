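"""Artificial-insertion grids over the input space and the prediction plots.

For each family x orientation combination, the normalized [0, 1] range of the
two continuous inputs (intron size, ERV-exon distance) is divided into
``n_units`` bins and the consolidated ensemble output is evaluated at every
bin midpoint, giving an n x n output matrix per combination (4 x 100 x 100 =
40,000 points in a full run). The rendered "prediction plot" is a heatmap of
those outputs in ordered color bins: x = normalized ERV-exon distance,
y = normalized intron size with large introns at the bottom, and grid cells
where the denormalized distance exceeds half the intron size masked as
geometrically infeasible (an insertion cannot be farther from the nearest
exon than the intron's midpoint), producing the characteristic triangle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ervpredict.ensemble import EnsembleModel, consolidate
from ervpredict.features import DISTANCE_CAP_BP, INTRON_CAP_BP, denormalize_length, encode_insertion

COMBOS = tuple((family, orientation) for family in ("IAP", "ETnMusD") for orientation in ("sense", "antisense"))

DEFAULT_COLOR_BINS = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))


@dataclass
class GridPrediction:
    family: str
    orientation: str
    grid_u_intron: np.ndarray  # (n,)
    grid_u_distance: np.ndarray  # (n,)
    outputs: np.ndarray  # (n, n), [intron index, distance index]

    @property
    def axis_bp(self) -> dict:
        """Denormalized bp values of the grid coordinates, for axis labels."""
        return {
            "intron_bp": denormalize_length(self.grid_u_intron, INTRON_CAP_BP),
            "distance_bp": denormalize_length(self.grid_u_distance, DISTANCE_CAP_BP),
        }


def make_grid(n_units: int = 100) -> dict:
    """Crossed input collection: 4 combos x n_units^2 midpoint coordinates.

    Continuous coordinates sit at bin midpoints u_i = (i - 0.5)/n_units,
    avoiding the degenerate endpoints 0 and 1 while keeping ``n_units`` cells.
    Returns {"u": midpoints, "combos": [{family, orientation, X}, ...]} where
    X has shape (n_units^2, 4) ordered intron-major.
    """
    if n_units < 2:
        raise ValueError(f"n_units must be at least 2, got {n_units}")
    u = (np.arange(1, n_units + 1) - 0.5) / n_units
    ui, ud = np.meshgrid(u, u, indexing="ij")  # intron-major
    combos = []
    for family, orientation in COMBOS:
        X = np.column_stack(
            [
                np.full(n_units**2, 1.0 if orientation == "sense" else 0.0),
                np.full(n_units**2, 1.0 if family == "ETnMusD" else 0.0),
                ui.ravel(),
                ud.ravel(),
            ]
        )
        combos.append({"family": family, "orientation": orientation, "X": X})
    return {"u": u, "n_units": n_units, "combos": combos}


def predict_grid(ensemble: EnsembleModel, grid: dict) -> list[GridPrediction]:
    """Consolidated output at every grid point, one GridPrediction per combo."""
    if ensemble.n_members == 0:
        raise ValueError("cannot predict from an empty ensemble")
    n = grid["n_units"]
    out = []
    for combo in grid["combos"]:
        scores = consolidate(ensemble, combo["X"])
        out.append(
            GridPrediction(
                family=combo["family"],
                orientation=combo["orientation"],
                grid_u_intron=grid["u"].copy(),
                grid_u_distance=grid["u"].copy(),
                outputs=scores.reshape(n, n),
            )
        )
    return out


def infeasible_mask(gp: GridPrediction) -> np.ndarray:
    """True where the cell's distance exceeds half its intron size in bp."""
    intron_bp = denormalize_length(gp.grid_u_intron, INTRON_CAP_BP)
    dist_bp = denormalize_length(gp.grid_u_distance, DISTANCE_CAP_BP)
    return dist_bp[None, :] > intron_bp[:, None] / 2.0


def render_prediction_plot(
    gp: GridPrediction,
    overlays: Sequence = (),
    color_bins: Sequence[float] = DEFAULT_COLOR_BINS,
    mask_infeasible: bool = True,
    path=None,
    mirror: bool = False,
    ax=None,
):
    """Render one prediction plot (heatmap + training-case overlays).

    Outputs are discretized into the ordered ``color_bins`` with a rainbow
    colormap. Positive overlays draw as filled cyan circles, negatives as
    filled white squares; an overlay whose family/orientation does not match
    the grid is rejected. With ``mirror`` the half-plot is duplicated
    symmetrically around the intron center. Writes ``path`` if given;
    returns the matplotlib Axes.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm

    edges = np.asarray(color_bins, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("color_bins must be strictly increasing")
    Z = np.ma.masked_array(gp.outputs, mask=infeasible_mask(gp) if mask_infeasible else False)
    u_d, u_i = gp.grid_u_distance, gp.grid_u_intron
    if mirror:
        Z = np.ma.concatenate([Z[:, ::-1], Z], axis=1)
        u_d = np.concatenate([-u_d[::-1], u_d])
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 4.2))
    cmap = plt.get_cmap("rainbow", len(edges) - 1)
    cmap = cmap.copy()
    cmap.set_bad("0.85")
    norm = BoundaryNorm(edges, cmap.N)
    mesh = ax.pcolormesh(u_d, u_i, Z, cmap=cmap, norm=norm, shading="nearest")
    for rec in overlays:
        if rec.family != gp.family or rec.orientation != gp.orientation:
            raise ValueError(
                f"overlay {rec.id!r} ({rec.family}/{rec.orientation}) does not match "
                f"the grid ({gp.family}/{gp.orientation})"
            )
        fv = encode_insertion(rec)
        marker, color = ("o", "cyan") if rec.label == "positive" else ("s", "white")
        ax.plot(fv.x_distance, fv.x_intron, marker=marker, color=color, markeredgecolor="black", markersize=6)
        if mirror:
            ax.plot(-fv.x_distance, fv.x_intron, marker=marker, color=color, markeredgecolor="black", markersize=6)
    ax.invert_yaxis()  # large introns at the bottom
    dist_ticks = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    intron_ticks = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    ax.set_xticks(dist_ticks if not mirror else np.concatenate([-dist_ticks[:0:-1], dist_ticks]))
    ax.set_yticks(intron_ticks)
    ax.set_xticklabels(
        [_fmt_bp(denormalize_length(abs(t), DISTANCE_CAP_BP)) for t in ax.get_xticks()]
    )
    ax.set_yticklabels([_fmt_bp(denormalize_length(t, INTRON_CAP_BP)) for t in intron_ticks])
    ax.set_xlabel("distance to nearest exon")
    ax.set_ylabel("intron size")
    ax.set_title(f"{gp.family}, {gp.orientation}")
    ax.figure.colorbar(mesh, ax=ax, ticks=edges, label="predicted likelihood")
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax


def _fmt_bp(bp: float) -> str:
    if bp >= 1000:
        return f"{bp / 1000:.0f} kb"
    return f"{bp:.0f} bp"


def grid_to_frame(gp: GridPrediction):
    """Long-format table (u_intron, u_distance, output) for TSV export."""
    import pandas as pd

    ui, ud = np.meshgrid(gp.grid_u_intron, gp.grid_u_distance, indexing="ij")
    return pd.DataFrame(
        {
            "family": gp.family,
            "orientation": gp.orientation,
            "u_intron": ui.ravel(),
            "u_distance": ud.ravel(),
            "output": gp.outputs.ravel(),
        }
    )
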