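"""Abundance surfaces and percent-population prioritization maps.

A fitted year model predicts, at every grid cell, the expected pair count
of a survey-segment-sized (~11 km^2) neighborhood centered there.  Cell
contributions rescale that window-scale prediction by cell_area/window_area
so the surface sums to a landscape total.  Yearly surfaces aggregate into
cellwise mean, SD, and max; cells ranked by predicted density are labeled
with the smallest cumulative population share (10%, 20%, ...) their
inclusion achieves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import WINDOW_AREA_KM2
from .grids import Grid, grids_aligned
from .modeling import YearModel


@dataclass
class AbundanceSurface:
    """Gridded predicted pair density (cell-contribution scale)."""

    label: str  # year as string, or "mean" | "sd" | "max"
    pairs: Grid

    @property
    def total(self) -> float:
        m = self.pairs.mask()
        return float(self.pairs.data[m].sum())


@dataclass
class PercentPopulationMap:
    bins: Grid  # labels in {10, 20, ..., 100}; nodata preserved
    summary: pd.DataFrame  # per-bin n_cells, duck_total, share


def predict_surface(
    model: YearModel,
    grid_stack: dict[str, Grid],
    window_area_km2: float = WINDOW_AREA_KM2,
) -> AbundanceSurface:
    """Apply a year model to every grid cell.

    The forest consumes the model's selected covariate rasters; the
    window-scale prediction P is rescaled to a per-cell contribution
    ``P * cell_area / window_area``.  Negative predictions floor at zero
    (regression forests cannot extrapolate below the observed minimum, so
    the floor is a formality).  Cells where any covariate is nodata are
    nodata.
    """
    missing = [v for v in model.variables if v not in grid_stack]
    if missing:
        raise ValueError(f"grid stack missing covariate rasters: {missing}")
    ref = grid_stack[model.variables[0]]
    layers = [grid_stack[v] for v in model.variables]
    if not grids_aligned(*layers):
        raise ValueError("covariate rasters are not aligned")
    valid = np.logical_and.reduce([g.mask() for g in layers])
    X = np.column_stack([g.data[valid] for g in layers])
    pred = model.forest.predict(X)
    pred = np.clip(pred, 0.0, None)
    scale = ref.cell_area_km2 / window_area_km2
    out = np.full(ref.data.shape, ref.nodata)
    out[valid] = pred * scale
    return AbundanceSurface(label=str(model.year), pairs=ref.like(out))


def aggregate_surfaces(
    surfaces: list[AbundanceSurface],
) -> tuple[AbundanceSurface, AbundanceSurface, AbundanceSurface]:
    """Cellwise mean, SD (population, divisor n), and max across years."""
    if len(surfaces) < 2:
        raise ValueError("need at least 2 yearly surfaces")
    grids = [s.pairs for s in surfaces]
    if not grids_aligned(*grids):
        raise ValueError("surfaces are on different grids")
    ref = grids[0]
    stack = np.stack([g.data for g in grids])
    valid = np.logical_and.reduce([g.mask() for g in grids])

    def masked(values: np.ndarray) -> Grid:
        out = np.where(valid, values, ref.nodata)
        return ref.like(out)

    return (
        AbundanceSurface("mean", masked(stack.mean(axis=0))),
        AbundanceSurface("sd", masked(stack.std(axis=0))),
        AbundanceSurface("max", masked(stack.max(axis=0))),
    )


def percent_population_bins(surface: AbundanceSurface, bin_width: int = 10) -> PercentPopulationMap:
    """Cumulative percent-population binning (first-crossing rule).

    Cells are walked in decreasing predicted density (ties broken by
    ascending linear cell index), accumulating population share.  Cells are
    assigned to bin b while the b% threshold is still unmet, so the cells
    labeled <= b form exactly the smallest decreasing-density area that
    contains b% of the predicted population.  Zero-density cells land in
    bin 100.
    """
    if 100 % bin_width != 0:
        raise ValueError("bin_width must divide 100")
    g = surface.pairs
    valid = g.mask()
    values = g.data[valid]
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero surface: percent-population bins undefined")
    flat_index = np.flatnonzero(valid.ravel())
    # descending value, ties by ascending linear index
    order = np.lexsort((flat_index, -values))
    cum_share = np.cumsum(values[order]) / total * 100.0
    prev_share = np.concatenate([[0.0], cum_share[:-1]])
    # a cell belongs to the smallest threshold not yet met when it is added
    labels = bin_width * (np.floor((prev_share + 1e-9) / bin_width) + 1)
    labels = np.clip(labels, bin_width, 100)
    labels[values[order] == 0] = 100

    bins_flat = np.full(g.data.size, g.nodata)
    bins_flat[flat_index[order]] = labels
    bins = g.like(bins_flat.reshape(g.data.shape))

    rows = []
    for b in range(bin_width, 101, bin_width):
        in_bin = labels == b
        rows.append(
            {
                "bin": b,
                "n_cells": int(in_bin.sum()),
                "duck_total": float(values[order][in_bin].sum()),
            }
        )
    summary = pd.DataFrame(rows)
    summary["share"] = summary["duck_total"] / total
    return PercentPopulationMap(bins=bins, summary=summary)
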