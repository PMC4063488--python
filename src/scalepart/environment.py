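"""Environmental raster layers: resampling, per-cell extraction, and variability.

A landscape is a set of :class:`EnvironmentalLayer` objects sharing one planar
km-based coordinate frame (origin at the lower-left corner, x east, y north).
Arrays are indexed ``grid[iy, ix]`` with ``iy = 0`` the *bottom* row, so that
row-major flattening enumerates cells from the lower-left corner — the cell
order used for community and environment matrices throughout.

Continuous variables aggregate by the block mean, categorical variables by the
block majority (modal class, ties to the lowest class code).  Elevation range
is derived during aggregation as block max − block min of the fine elevation
layer.  The coefficient of variation of a variable within a sampling grid is
computed on the grid's cell values; the default convention is sd/mean
(population sd), with variance/mean available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0

#: Aggregation methods understood by the resampling engine.
_AGG_METHODS = ("mean", "majority", "range")


@dataclass
class EnvironmentalLayer:
    """One environmental variable on a regular square-celled raster.

    Parameters
    ----------
    name:
        Variable name (e.g. ``"temperature"``, ``"lulc"``, ``"pct_forest"``).
    kind:
        ``"continuous"`` or ``"categorical"``.  Categorical layers hold
        integer class codes.
    grid:
        2-D array ``grid[iy, ix]``, ``iy = 0`` at the bottom (origin) row.
    cell_area:
        Area of one cell in km²; the cell side is ``sqrt(cell_area)``.
    origin:
        ``(x, y)`` of the lower-left corner in km.
    nodata:
        Sentinel for missing values (continuous layers use NaN internally).
    """

    name: str
    kind: str
    grid: np.ndarray
    cell_area: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("layer grid must be 2-D")

    @property
    def cell_side(self) -> float:
        return math.sqrt(self.cell_area)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        ny, nx = self.grid.shape
        x0, y0 = self.origin
        s = self.cell_side
        return (x0, y0, x0 + nx * s, y0 + ny * s)


@dataclass(frozen=True)
class VariableGroup:
    """A named, disjoint group of analysis variables (climate, topography, lulc, ndvi)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"variable group {self.name!r} has no members")


def default_variable_groups(lulc_class_names: tuple[str, ...]) -> list[VariableGroup]:
    """The four-group split used by the analysis.

    climate: mean annual temperature, temperature seasonality, mean annual
    precipitation, precipitation seasonality; topography: elevation and
    elevation range; lulc: distance to urban, population density, and the
    per-class percent covers; ndvi: NDVI.
    """
    return [
        VariableGroup(
            "climate",
            (
                "temperature",
                "temperature_seasonality",
                "precipitation",
                "precipitation_seasonality",
            ),
        ),
        VariableGroup("topography", ("elevation", "elevation_range")),
        VariableGroup(
            "lulc",
            ("distance_to_urban", "population_density")
            + tuple(f"pct_{c}" for c in lulc_class_names),
        ),
        VariableGroup("ndvi", ("ndvi",)),
    ]


# ---------------------------------------------------------------------------
# Block resampling (integer aggregation factor)
# ---------------------------------------------------------------------------


def _integer_factor(layer: EnvironmentalLayer, target_cell_area: float) -> int:
    if target_cell_area < layer.cell_area:
        raise ValueError("target_cell_area must be >= the layer cell_area")
    f = math.sqrt(target_cell_area / layer.cell_area)
    fi = round(f)
    if fi < 1 or abs(f - fi) > 1e-9 * max(1.0, fi):
        raise ValueError(
            f"non-integer aggregation factor {f:.6g} for {layer.name!r}: "
            "choose a target grain whose cell side is an integer multiple of "
            "the layer's cell side (or aggregate via aggregate_to_lattice)"
        )
    return fi


def _blocks(a: np.ndarray, f: int) -> np.ndarray:
    """Reshape to (ny, nx, f*f) blocks, trimming rows/cols not filling a block."""
    ny, nx = a.shape[0] // f, a.shape[1] // f
    if ny == 0 or nx == 0:
        raise ValueError("aggregation factor exceeds layer dimensions")
    trimmed = a[: ny * f, : nx * f]
    return trimmed.reshape(ny, f, nx, f).swapaxes(1, 2).reshape(ny, nx, f * f)


def _majority(block_values: np.ndarray) -> np.ndarray:
    """Modal class per block; ties broken by the lowest class code."""
    ny, nx, _ = block_values.shape
    codes = block_values.astype(np.int64)
    lo = codes.min()
    codes -= lo
    k = int(codes.max()) + 1
    flat = codes.reshape(-1, codes.shape[-1])
    counts = np.zeros((flat.shape[0], k), dtype=np.int64)
    rows = np.repeat(np.arange(flat.shape[0]), flat.shape[1])
    np.add.at(counts, (rows, flat.ravel()), 1)
    # argmax returns the first (= lowest code) maximum
    return (counts.argmax(axis=1) + lo).reshape(ny, nx)


def resample_layer(
    layer: EnvironmentalLayer,
    target_cell_area: float,
    how: str | None = None,
) -> EnvironmentalLayer:
    """Aggregate a layer to a coarser grain by an integer linear factor.

    Continuous layers aggregate by the block mean (NaN/nodata ignored),
    categorical layers by the block majority with ties broken toward the
    lowest class code.  ``how="range"`` yields block max − block min (used to
    derive elevation range).  Rows/columns that do not fill a whole block are
    trimmed.
    """
    f = _integer_factor(layer, target_cell_area)
    if how is None:
        how = "majority" if layer.kind == "categorical" else "mean"
    if how not in _AGG_METHODS:
        raise ValueError(f"unknown aggregation method {how!r}")
    if f == 1 and how != "range":
        return replace(layer, grid=layer.grid.copy())

    if how == "majority":
        out = _majority(_blocks(layer.grid, f))
        kind = "categorical"
    else:
        vals = _blocks(np.asarray(layer.grid, dtype=float), f)
        vals = np.where(vals == layer.nodata, np.nan, vals)
        with np.errstate(invalid="ignore"):
            if how == "mean":
                out = np.nanmean(vals, axis=-1)
            else:  # range
                out = np.nanmax(vals, axis=-1) - np.nanmin(vals, axis=-1)
        kind = "continuous"
    name = layer.name if how != "range" else f"{layer.name}_range"
    return EnvironmentalLayer(
        name=name,
        kind=kind,
        grid=out,
        cell_area=layer.cell_area * f * f,
        origin=layer.origin,
        nodata=layer.nodata,
    )


def derive_lulc_percent(
    layer: EnvironmentalLayer,
    target_cell_area: float,
    class_names: dict[int, str],
) -> dict[str, EnvironmentalLayer]:
    """Per-class percent-cover layers at a coarser grain.

    Each output layer ``pct_<class>`` holds the percentage of fine pixels of
    that class inside each coarse cell; across classes the percentages sum to
    100 in every cell.  Unknown class codes raise an error listing them.
    """
    if layer.kind != "categorical":
        raise ValueError("derive_lulc_percent requires a categorical layer")
    codes = np.unique(layer.grid)
    unknown = sorted(int(c) for c in codes if int(c) not in class_names)
    if unknown:
        raise ValueError(f"unknown LULC class codes: {unknown}")
    f = _integer_factor(layer, target_cell_area)
    blocks = _blocks(layer.grid, f)
    out: dict[str, EnvironmentalLayer] = {}
    for code, cname in sorted(class_names.items()):
        pct = 100.0 * (blocks == code).mean(axis=-1)
        out[f"pct_{cname}"] = EnvironmentalLayer(
            name=f"pct_{cname}",
            kind="continuous",
            grid=pct,
            cell_area=layer.cell_area * f * f,
            origin=layer.origin,
            nodata=layer.nodata,
        )
    return out


# ---------------------------------------------------------------------------
# Lattice aggregation (arbitrary, possibly irrational, cell side)
# ---------------------------------------------------------------------------


def aggregate_to_lattice(
    layer: EnvironmentalLayer,
    cell_side: float,
    how: str = "mean",
) -> EnvironmentalLayer:
    """Aggregate fine pixels onto a square cell lattice of side ``cell_side`` km.

    Pixels are assigned to the lattice cell containing their *center*
    (half-open intervals), which reduces to exact block aggregation when
    ``cell_side`` is an integer multiple of the pixel side and remains exact
    bookkeeping when it is not (the doubling-area grain series makes most cell
    sides irrational multiples of the pixel side).  Cells that extend past the
    layer edge are dropped.
    """
    if cell_side < layer.cell_side - 1e-12:
        raise ValueError("lattice cell_side must be >= the layer pixel side")
    ny, nx = layer.grid.shape
    px = layer.cell_side
    n_cx = int(math.floor(nx * px / cell_side + 1e-9))
    n_cy = int(math.floor(ny * px / cell_side + 1e-9))
    if n_cx == 0 or n_cy == 0:
        raise ValueError("lattice cell_side exceeds layer extent")

    # lattice cell index of every pixel center
    cx = np.floor((np.arange(nx) + 0.5) * px / cell_side).astype(np.int64)
    cy = np.floor((np.arange(ny) + 0.5) * px / cell_side).astype(np.int64)
    in_x = cx < n_cx
    in_y = cy < n_cy
    cell_ix = np.add.outer(cy[in_y] * n_cx, cx[in_x]).ravel()  # (ny_in*nx_in,)
    vals = layer.grid[np.ix_(in_y, in_x)].ravel()
    n_cells = n_cy * n_cx

    if how == "majority":
        codes = vals.astype(np.int64)
        lo = codes.min()
        k = int(codes.max() - lo) + 1
        counts = np.zeros((n_cells, k), dtype=np.int64)
        np.add.at(counts, (cell_ix, codes - lo), 1)
        out = (counts.argmax(axis=1) + lo).astype(float).reshape(n_cy, n_cx)
        kind = "categorical"
    else:
        fvals = np.asarray(vals, dtype=float)
        fvals = np.where(fvals == layer.nodata, np.nan, fvals)
        ok = np.isfinite(fvals)
        cnt = np.bincount(cell_ix[ok], minlength=n_cells).astype(float)
        if how == "mean":
            tot = np.bincount(cell_ix[ok], weights=fvals[ok], minlength=n_cells)
            with np.errstate(invalid="ignore"):
                out = (tot / cnt).reshape(n_cy, n_cx)
        elif how == "range":
            mx = np.full(n_cells, -np.inf)
            mn = np.full(n_cells, np.inf)
            np.maximum.at(mx, cell_ix[ok], fvals[ok])
            np.minimum.at(mn, cell_ix[ok], fvals[ok])
            out = np.where(cnt > 0, mx - mn, np.nan).reshape(n_cy, n_cx)
        else:
            raise ValueError(f"unknown aggregation method {how!r}")
        kind = "continuous"

    name = layer.name if how != "range" else f"{layer.name}_range"
    return EnvironmentalLayer(
        name=name,
        kind=kind,
        grid=out,
        cell_area=cell_side * cell_side,
        origin=layer.origin,
        nodata=layer.nodata,
    )


def lattice_percent_cover(
    layer: EnvironmentalLayer,
    cell_side: float,
    class_names: dict[int, str],
) -> dict[str, EnvironmentalLayer]:
    """Percent cover per LULC class on an arbitrary cell lattice (see above)."""
    if layer.kind != "categorical":
        raise ValueError("percent cover requires a categorical layer")
    codes = np.unique(layer.grid)
    unknown = sorted(int(c) for c in codes if int(c) not in class_names)
    if unknown:
        raise ValueError(f"unknown LULC class codes: {unknown}")
    out: dict[str, EnvironmentalLayer] = {}
    for code, cname in sorted(class_names.items()):
        ind = replace(
            layer, name=f"pct_{cname}", kind="continuous",
            grid=(layer.grid == code).astype(float) * 100.0,
        )
        out[f"pct_{cname}"] = aggregate_to_lattice(ind, cell_side, how="mean")
    return out


# ---------------------------------------------------------------------------
# Environment matrix extraction
# ---------------------------------------------------------------------------


def extract_environment(layers: dict[str, EnvironmentalLayer], grid) -> pd.DataFrame:
    """Per-cell environment matrix for one sampling grid.

    ``layers`` must already be aggregated to the grid's grain and share the
    grid's lattice (anchored at the same origin).  Returns a DataFrame with
    one row per cell in row-major order from the lower-left corner (1024 rows
    for the standard 32×32 grid) and one column per variable.
    """
    n = grid.n_cells_side
    frames = {}
    for name, layer in layers.items():
        if abs(layer.cell_side - grid.scale.cell_side) > 1e-6 * grid.scale.cell_side:
            raise ValueError(
                f"layer {name!r} grain does not match the sampling grid grain"
            )
        i0 = int(round((grid.origin[0] - layer.origin[0]) / layer.cell_side))
        j0 = int(round((grid.origin[1] - layer.origin[1]) / layer.cell_side))
        ny, nx = layer.grid.shape
        if i0 < 0 or j0 < 0 or i0 + n > nx or j0 + n > ny:
            raise ValueError(
                f"sampling grid {grid.grid_id!r} extends beyond layer {name!r}"
            )
        window = layer.grid[j0 : j0 + n, i0 : i0 + n]
        frames[name] = np.asarray(window, dtype=float).ravel()
    return pd.DataFrame(frames, index=pd.RangeIndex(n * n, name="cell"))


# ---------------------------------------------------------------------------
# Coefficient of variation
# ---------------------------------------------------------------------------


def compute_cv(values, convention: str = "sd_mean") -> float:
    """Coefficient of variation of a grid's cell values for one variable.

    ``sd_mean`` (default) is the standard CV, population sd divided by the
    mean; ``var_mean`` divides the population variance by the mean instead.
    Returns NaN (flagged undefined) when the mean is zero; callers exclude
    such records from downstream regressions.
    """
    if convention not in ("sd_mean", "var_mean"):
        raise ValueError(f"unknown CV convention {convention!r}")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("compute_cv requires at least 2 finite values")
    m = v.mean()
    if m == 0.0:
        return float("nan")
    spread = v.std(ddof=0) if convention == "sd_mean" else v.var(ddof=0)
    return float(spread / m)


def cv_table(
    env: pd.DataFrame,
    grid_id: str,
    scale_index: int,
    convention: str = "sd_mean",
) -> pd.DataFrame:
    """Per-variable CV records for one sampling grid's environment matrix."""
    rows = []
    for var in env.columns:
        vals = env[var].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        cv = compute_cv(vals, convention) if vals.size >= 2 else float("nan")
        rows.append(
            {
                "grid_id": grid_id,
                "scale": scale_index,
                "variable": var,
                "cv": cv,
                "convention": convention,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plain-text raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------


def write_ascii_grid(layer: EnvironmentalLayer, path) -> None:
    """Write a layer as an ESRI ASCII grid (rows top-down, plain text)."""
    ny, nx = layer.grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {layer.origin[0]:.10g}\n")
        fh.write(f"yllcorner {layer.origin[1]:.10g}\n")
        fh.write(f"cellsize {layer.cell_side:.10g}\n")
        fh.write(f"NODATA_value {layer.nodata:.10g}\n")
        data = np.asarray(layer.grid, dtype=float)
        data = np.where(np.isfinite(data), data, layer.nodata)
        for row in data[::-1]:  # ASCII grids store the top row first
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path, name: str, kind: str = "continuous") -> EnvironmentalLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    nx, ny = int(header["ncols"]), int(header["nrows"])
    data = np.loadtxt(lines[6:])
    data = np.atleast_2d(data)
    if data.shape != (ny, nx):
        raise ValueError(f"grid body shape {data.shape} does not match header")
    grid = data[::-1].copy()  # back to bottom-row-first
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    if kind == "categorical":
        grid = grid.astype(np.int64)
    else:
        grid = np.where(grid == nodata, np.nan, grid)
    return EnvironmentalLayer(
        name=name,
        kind=kind,
        grid=grid,
        cell_area=header["cellsize"] ** 2,
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=nodata,
    )
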