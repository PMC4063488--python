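"""Sampling-grid construction across a doubling series of spatial scales.

Scale has two components: *grain*, the area of one grid cell, and *extent*,
the area of one whole sampling grid.  Every sampling grid is a 32 × 32 window
of square cells, so extent = 1024 × grain at every scale, and the grain
doubles in area between consecutive scales (10, 20, 40, ... km² in the
reference design).  Grids tile the study area without overlap, anchored at
its lower-left corner; a window that does not fit entirely inside the bounds
is discarded.

A grid qualifies for ordination when it contains at least 30 cells holding
more than one occurrence record (nonsingleton cells) and records of at least
six different species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_CELLS_SIDE = 32
CELLS_PER_GRID = N_CELLS_SIDE * N_CELLS_SIDE  # 1024
MIN_NONSINGLETON_CELLS = 30
MIN_SPECIES = 6


@dataclass(frozen=True)
class ScaleSpec:
    """One rung of the scale series: index, grain (km²) and extent (km²)."""

    index: int
    grain: float
    extent: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.grain <= 0:
            raise ValueError("grain must be positive")
        if self.extent == 0.0:
            object.__setattr__(self, "extent", CELLS_PER_GRID * self.grain)
        if abs(self.extent - CELLS_PER_GRID * self.grain) > 1e-6 * self.extent:
            raise ValueError("extent must equal 1024 × grain")

    @property
    def cell_side(self) -> float:
        """Side of one grid cell in km."""
        return math.sqrt(self.grain)

    @property
    def extent_side(self) -> float:
        """Side of one whole sampling grid in km."""
        return N_CELLS_SIDE * self.cell_side


@dataclass
class SamplingGrid:
    """One 32×32-cell window with its community matrix.

    ``community`` is a cells × species DataFrame of occurrence counts with a
    full 1024-row index in row-major cell order from the lower-left corner;
    it is None until :func:`aggregate_occurrences` fills it.
    """

    grid_id: str
    scale: ScaleSpec
    origin: tuple[float, float]
    community: pd.DataFrame | None = None
    qualified: bool | None = None
    n_cells_side: int = N_CELLS_SIDE

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        side = self.scale.extent_side
        return (
            self.origin[0],
            self.origin[1],
            self.origin[0] + side,
            self.origin[1] + side,
        )


def build_scale_series(base_grain: float, n_scales: int) -> list[ScaleSpec]:
    """Doubling-area grain series: grain_k = base_grain · 2^(k−1), extent = 1024·grain.

    With base_grain = 10 km² and 11 scales this reproduces the reference
    series from (10; 10,240) km² up to (10,240; 10,485,760) km².
    """
    if base_grain <= 0:
        raise ValueError("base_grain must be positive")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    return [ScaleSpec(index=k, grain=base_grain * 2 ** (k - 1)) for k in range(1, n_scales + 1)]


def tile_grids(
    study_bounds: tuple[float, float, float, float],
    scale: ScaleSpec,
) -> list[SamplingGrid]:
    """Non-overlapping tiling of empty sampling grids over the study area.

    Anchored at the study-area lower-left corner; windows extending beyond
    the bounds are discarded (no partial grids, no sliding windows).
    """
    xmin, ymin, xmax, ymax = study_bounds
    side = scale.extent_side
    eps = 1e-9 * side
    nx = int(math.floor((xmax - xmin) / side + eps))
    ny = int(math.floor((ymax - ymin) / side + eps))
    grids = [
        SamplingGrid(
            grid_id=f"s{scale.index}_x{i}_y{j}",
            scale=scale,
            origin=(xmin + i * side, ymin + j * side),
        )
        for j in range(ny)
        for i in range(nx)
    ]
    if not grids:
        logger.warning(
            "no sampling grid of extent %.6g km² fits inside the study bounds", scale.extent
        )
    return grids


def aggregate_occurrences(records: pd.DataFrame, grid: SamplingGrid) -> SamplingGrid:
    """Fill a grid's community matrix from occurrence records.

    Each record falls in exactly one cell by half-open intervals
    ``[low, high)`` on both axes (a record exactly on an interior boundary
    belongs to the higher-index cell).  Records outside the grid are ignored
    (counted in the log).  The sum of the community matrix equals the number
    of in-grid records.
    """
    x0, y0, x1, y1 = grid.bounds
    s = grid.scale.cell_side
    n = grid.n_cells_side

    x = records["lon"].to_numpy(dtype=float)
    y = records["lat"].to_numpy(dtype=float)
    inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
    n_out = int((~inside).sum())
    if n_out:
        logger.debug("grid %s: %d records outside bounds ignored", grid.grid_id, n_out)

    ix = np.floor((x[inside] - x0) / s).astype(np.int64)
    iy = np.floor((y[inside] - y0) / s).astype(np.int64)
    # guard against float round-off pushing a boundary record past the last cell
    ix = np.clip(ix, 0, n - 1)
    iy = np.clip(iy, 0, n - 1)
    cell = iy * n + ix

    species = records.loc[inside, "species_id"].to_numpy()
    counts = (
        pd.DataFrame({"cell": cell, "species_id": species})
        .groupby(["cell", "species_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    community = counts.reindex(pd.RangeIndex(n * n, name="cell"), fill_value=0).astype(np.int64)
    community.columns.name = "species_id"
    grid.community = community
    return grid


def qualify_grid(
    grid: SamplingGrid,
    min_nonsingleton_cells: int = MIN_NONSINGLETON_CELLS,
    min_species: int = MIN_SPECIES,
) -> tuple[bool, str]:
    """Apply the data-sufficiency thresholds to a filled grid.

    Qualified iff at least ``min_nonsingleton_cells`` cells hold two or more
    records (summed over species) and at least ``min_species`` species occur
    in the grid.  Returns the flag and a human-readable reason, and stores
    the flag on the grid.
    """
    if grid.community is None:
        raise ValueError("grid community must be filled before qualification")
    cell_totals = grid.community.sum(axis=1)
    n_nonsingleton = int((cell_totals >= 2).sum())
    n_species = int((grid.community.sum(axis=0) >= 1).sum())
    ok_cells = n_nonsingleton >= min_nonsingleton_cells
    ok_species = n_species >= min_species
    qualified = ok_cells and ok_species
    if qualified:
        reason = f"qualified ({n_nonsingleton} nonsingleton cells, {n_species} species)"
    elif not ok_cells:
        reason = (
            f"rejected: {n_nonsingleton} nonsingleton cells < {min_nonsingleton_cells}"
        )
    else:
        reason = f"rejected: {n_species} species < {min_species}"
    grid.qualified = qualified
    return qualified, reason


def grid_summary(grids: list[SamplingGrid]) -> pd.DataFrame:
    """Bookkeeping table per grid: origin, qualification, species and cell counts."""
    rows = []
    for g in grids:
        comm = g.community
        cell_totals = comm.sum(axis=1) if comm is not None else pd.Series(dtype=int)
        rows.append(
            {
                "grid_id": g.grid_id,
                "scale": g.scale.index,
                "origin_x": g.origin[0],
                "origin_y": g.origin[1],
                "qualified": g.qualified,
                "n_records": int(cell_totals.sum()) if comm is not None else 0,
                "n_species": int((comm.sum(axis=0) >= 1).sum()) if comm is not None else 0,
                "n_nonsingleton_cells": int((cell_totals >= 2).sum()) if comm is not None else 0,
            }
        )
    return pd.DataFrame(rows)
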