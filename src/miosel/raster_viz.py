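"""Model-ensemble raster plots and residual-SD-versus-size tables.

A raster plot lays out a ranked model ensemble as a grid: one row per model,
one column per predictor, with pixel colour encoding the sign (blue negative,
red positive) and intensity the magnitude of each coefficient.  To make
magnitudes comparable across predictors, coefficients are expressed on a
common predictor scale — by default each centered predictor is rescaled to
unit Euclidean norm — and the whole grid is normalized by its largest
absolute entry.  Predictors that recur across the best models form vertical
bands, which is what makes the ensemble's consensus visible at a glance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ModelRecord
from .subset_select import StandardizedDesign

__all__ = ["RasterGrid", "build_raster", "render_raster", "rsd_vs_size", "plot_rsd"]


@dataclass
class RasterGrid:
    """Signed intensities in [-1, 1]; rows grouped by size (largest first),
    within a size ordered by nondecreasing RSS."""

    cells: np.ndarray
    row_order: list[ModelRecord]
    column_order: list[int]

    def __post_init__(self) -> None:
        if np.abs(self.cells).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("raster intensities must lie in [-1, 1]")


def _ordered_models(models: list[ModelRecord]) -> list[ModelRecord]:
    return sorted(models, key=lambda m: (-m.n_terms, m.rss, m.sorted_support))


def build_raster(
    models: list[ModelRecord],
    design: StandardizedDesign,
    scaling: str = "unit_norm",
) -> RasterGrid:
    """Assemble the coefficient grid for a ranked ensemble.

    ``scaling="unit_norm"`` rescales each SD-1 coefficient to the
    unit-Euclidean-norm predictor convention (a factor sqrt(N-1));
    ``scaling="sd"`` keeps the SD-1 scale.  Both differ only by a global
    factor, which the final max-normalization removes.
    """
    if not models:
        raise ValueError("no models to plot")
    if scaling not in ("unit_norm", "sd"):
        raise ValueError(f"unknown scaling {scaling!r}")
    ordered = _ordered_models(models)
    cols = list(design.predictor_ids)
    col_index = {pid: j for j, pid in enumerate(cols)}
    cells = np.zeros((len(ordered), len(cols)))
    factor = math.sqrt(design.n - 1) if scaling == "unit_norm" else 1.0
    for i, m in enumerate(ordered):
        for pid, beta in m.coefficients_std.items():
            cells[i, col_index[pid]] = beta * factor
    peak = np.abs(cells).max()
    if peak > 0:
        cells = cells / peak
    return RasterGrid(cells=cells, row_order=ordered, column_order=cols)


def render_raster(grid: RasterGrid, path, dpi: int = 150) -> None:
    """Write the raster as an image: blue-white-red diverging map, axes
    labeled by predictor ID and model rank."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n_models, t = grid.cells.shape
    fig, ax = plt.subplots(figsize=(max(4.0, min(12.0, t / 60)), max(3.0, n_models / 12)))
    ax.imshow(
        grid.cells,
        cmap="bwr",
        vmin=-1,
        vmax=1,
        aspect="auto",
        interpolation="nearest",
    )
    ax.set_xlabel("predictor ID")
    ax.set_ylabel("model (grouped by size, best first)")
    sizes = [m.n_terms for m in grid.row_order]
    boundaries = [i for i in range(1, n_models) if sizes[i] != sizes[i - 1]]
    for b in boundaries:
        ax.axhline(b - 0.5, color="0.6", lw=0.6)
    step = max(1, t // 12)
    ax.set_xticks(range(0, t, step))
    ax.set_xticklabels([grid.column_order[j] for j in range(0, t, step)], fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi, metadata={"Software": ""} if str(path).endswith(".png") else None)
    plt.close(fig)


def rsd_vs_size(models: list[ModelRecord], design: StandardizedDesign) -> pd.DataFrame:
    """Residual SD on the original response scale for each ranked model.

    RSS on the standardized scale converts back through the response SD;
    the divisor is the residual degrees of freedom N - p - 1.
    """
    rows = []
    for m in _ordered_models(models):
        df_resid = design.n - m.n_terms - 1
        if df_resid <= 0:
            raise ValueError(f"no residual degrees of freedom for size {m.n_terms}")
        rss_orig = m.rss * design.response_scale**2
        rows.append(
            {
                "n_terms": m.n_terms,
                "rank_within_size": m.rank_within_size,
                "residual_sd": math.sqrt(rss_orig / df_resid),
            }
        )
    return pd.DataFrame(rows)


def plot_rsd(table: pd.DataFrame, path, dpi: int = 150) -> None:
    """Scatter residual SD against model size (the ensemble's elbow plot)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(table["n_terms"], table["residual_sd"], "o", ms=4, alpha=0.7)
    ax.set_xlabel("number of terms")
    ax.set_ylabel("residual SD (original units)")
    ax.set_xticks(sorted(table["n_terms"].unique()))
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
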