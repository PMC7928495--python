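"""Environmental raster stacks: reading, sampling, and collinearity reporting.

Layers are single-band ESRI ASCII grids (``.asc``) on a common geographic
grid. A stack is held as an :class:`EnvGrid`: named 2-D arrays sharing one
nodata mask and one geotransform. Grid indexing is 0-based, row-major, with
(row 0, col 0) at the north-west corner; point-to-cell mapping uses
half-open cell intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "EnvGrid",
    "CollinearityReport",
    "ExtractionResult",
    "AlignmentError",
    "ExtentError",
    "CapacityError",
    "read_env_grid",
    "read_ascii_grid",
    "write_ascii_grid",
    "extract",
    "sample_background",
    "collinearity",
]


class AlignmentError(ValueError):
    """Rasters do not share a grid (shape, cell size, or origin)."""


class ExtentError(ValueError):
    """A clip extent does not intersect the raster, or all points fall outside."""


class CapacityError(ValueError):
    """More samples requested than valid cells available."""


@dataclass
class EnvGrid:
    """An aligned stack of named predictor layers.

    Parameters
    ----------
    layer_names : list of str
        Unique layer identifiers, in stack order (e.g. ``bio01``..``bio19``).
    values : ndarray, shape (n_layers, n_rows, n_cols)
        Layer data. Cells under ``nodata_mask`` carry arbitrary values.
    nodata_mask : ndarray of bool, shape (n_rows, n_cols)
        True where the cell is nodata in *any* layer (union policy).
    xllcorner, yllcorner : float
        Coordinates of the outer corner of the lower-left cell, in degrees.
    cellsize : float
        Square cell edge, in degrees; > 0.
    crs_id : str
        Text CRS code; informational only (inputs must be pre-aligned).
    """

    layer_names: list[str]
    values: np.ndarray
    nodata_mask: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_layers, n_rows, n_cols)")
        if len(self.layer_names) != self.values.shape[0]:
            raise ValueError("layer_names length does not match values")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer names must be unique")
        if self.nodata_mask.shape != self.values.shape[1:]:
            raise AlignmentError("mask shape does not match layer shape")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.layer_names.index(name)]

    def select(self, names: Sequence[str]) -> "EnvGrid":
        """Sub-stack with the given layers, sharing mask and geometry."""
        idx = [self.layer_names.index(n) for n in names]
        return EnvGrid(list(names), self.values[idx], self.nodata_mask,
                       self.xllcorner, self.yllcorner, self.cellsize, self.crs_id)

    def cell_of(self, lon: float | np.ndarray, lat: float | np.ndarray):
        """Map coordinates to (row, col); may fall outside the grid."""
        col = np.floor((np.asarray(lon) - self.xllcorner) / self.cellsize).astype(int)
        nrows = self.shape[0]
        row = nrows - 1 - np.floor(
            (np.asarray(lat) - self.yllcorner) / self.cellsize).astype(int)
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        """Coordinates of cell centres for (row, col) indices."""
        nrows = self.shape[0]
        lon = self.xllcorner + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.yllcorner + (nrows - np.asarray(row) - 0.5) * self.cellsize
        return lon, lat

    def valid_table(self) -> pd.DataFrame:
        """Valid cells as a DataFrame with one column per layer."""
        ok = ~self.nodata_mask
        return pd.DataFrame(
            {n: self.values[i][ok] for i, n in enumerate(self.layer_names)})


@dataclass
class ExtractionResult:
    """Values extracted at points, with a record of dropped points."""

    values: np.ndarray            # (n_kept, n_layers)
    kept_index: np.ndarray        # indices into the input point list
    dropped_index: np.ndarray
    dropped_reason: list[str]     # parallel to dropped_index

    def report(self) -> pd.DataFrame:
        return pd.DataFrame({"point_index": self.dropped_index,
                             "reason": self.dropped_reason})


@dataclass
class CollinearityReport:
    """Pairwise Pearson structure and per-variable VIF of a predictor matrix."""

    names: list[str]
    pairwise_r: np.ndarray
    pairwise_r2: np.ndarray = field(init=False)
    vif: np.ndarray = None  # type: ignore[assignment]
    r_threshold: float = 0.8
    r2_threshold: float = 0.8
    vif_threshold: float = 10.0

    def __post_init__(self) -> None:
        self.pairwise_r2 = self.pairwise_r ** 2

    @property
    def r_flags(self) -> np.ndarray:
        off = ~np.eye(len(self.names), dtype=bool)
        return (np.abs(self.pairwise_r) > self.r_threshold) & off

    @property
    def vif_flags(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.vif > self.vif_threshold

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per ordered pair plus a VIF column."""
        rows = []
        for i, a in enumerate(self.names):
            for j, b in enumerate(self.names):
                if j <= i:
                    continue
                rows.append({"var1": a, "var2": b,
                             "r": self.pairwise_r[i, j],
                             "r2": self.pairwise_r2[i, j],
                             "flag_r": bool(self.r_flags[i, j]),
                             "flag_r2": bool(self.pairwise_r2[i, j] > self.r2_threshold)})
        pairs = pd.DataFrame(rows)
        vifs = pd.DataFrame({"variable": self.names, "vif": self.vif,
                             "flag_vif": self.vif_flags})
        return pairs.merge(vifs, left_on="var1", right_on="variable", how="left")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def read_ascii_grid(path: str | Path):
    """Read one ``.asc`` file; returns (array, nodata_mask, header dict)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not _is_number(parts[1]):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        else:
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    if "xllcenter" in header:  # corner registration is canonical internally
        header["xllcorner"] = header.pop("xllcenter") - header["cellsize"] / 2
        header["yllcorner"] = header.pop("yllcenter") - header["cellsize"] / 2
    nodata = header.get("nodata_value")
    mask = np.zeros_like(data, dtype=bool) if nodata is None else data == nodata
    return data, mask, header


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_ascii_grid(path: str | Path, array: np.ndarray,
                     xllcorner: float, yllcorner: float, cellsize: float,
                     nodata_mask: np.ndarray | None = None,
                     nodata_value: float = -9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid."""
    array = np.asarray(array, dtype=float)
    out = array.copy()
    if nodata_mask is not None:
        out[nodata_mask] = nodata_value
    nrows, ncols = out.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n"
                 f"xllcorner {xllcorner!r}\nyllcorner {yllcorner!r}\n"
                 f"cellsize {cellsize!r}\nNODATA_value {nodata_value!r}\n")
        np.savetxt(fh, out, fmt="%.10g")


def read_env_grid(paths: Sequence[str | Path],
                  clip_extent: tuple[float, float, float, float] | None = None,
                  layer_names: Sequence[str] | None = None,
                  crs_id: str = "EPSG:4326") -> EnvGrid:
    """Read a stack of aligned single-band ASCII grids into an :class:`EnvGrid`.

    Parameters
    ----------
    paths : sequence of path
        One file per layer; order defines stack order.
    clip_extent : (min_lon, min_lat, max_lon, max_lat), optional
        Bounding box to clip to, in grid coordinates. Cells whose centre
        falls inside the box are retained.
    layer_names : sequence of str, optional
        Defaults to file stems.

    The nodata mask is the union across layers: a cell nodata anywhere is
    nodata everywhere.
    """
    if len(paths) == 0:
        raise ValueError("at least one raster path is required")
    names = list(layer_names) if layer_names else [Path(p).stem for p in paths]
    arrays, masks = [], []
    ref_header = None
    for p in paths:
        data, mask, header = read_ascii_grid(p)
        if ref_header is None:
            ref_header = header
        else:
            same = (data.shape == arrays[0].shape
                    and np.isclose(header["cellsize"], ref_header["cellsize"])
                    and np.isclose(header["xllcorner"], ref_header["xllcorner"])
                    and np.isclose(header["yllcorner"], ref_header["yllcorner"]))
            if not same:
                raise AlignmentError(f"raster {p} is not aligned with {paths[0]}")
        arrays.append(data)
        masks.append(mask)
    values = np.stack(arrays)
    union_mask = np.any(np.stack(masks), axis=0)
    xll, yll = ref_header["xllcorner"], ref_header["yllcorner"]
    cs = ref_header["cellsize"]
    if clip_extent is not None:
        min_lon, min_lat, max_lon, max_lat = clip_extent
        nrows, ncols = values.shape[1:]
        lon_c = xll + (np.arange(ncols) + 0.5) * cs
        lat_c = yll + (np.arange(nrows)[::-1] + 0.5) * cs
        cols = np.flatnonzero((lon_c >= min_lon) & (lon_c <= max_lon))
        rows = np.flatnonzero((lat_c >= min_lat) & (lat_c <= max_lat))
        if cols.size == 0 or rows.size == 0:
            raise ExtentError("clip extent does not intersect the raster")
        values = values[:, rows.min():rows.max() + 1, cols.min():cols.max() + 1]
        union_mask = union_mask[rows.min():rows.max() + 1, cols.min():cols.max() + 1]
        xll = xll + cols.min() * cs
        yll = yll + (nrows - 1 - rows.max()) * cs
    return EnvGrid(names, values, union_mask, xll, yll, cs, crs_id)


# ---------------------------------------------------------------------------
# Sampling and extraction

def extract(grid: EnvGrid, points: Sequence[tuple[float, float]]) -> ExtractionResult:
    """Extract layer values at (lon, lat) points.

    Points outside the extent or on nodata cells are dropped and reported.
    Raises :class:`ExtentError` if no point is valid.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    row, col = grid.cell_of(pts[:, 0], pts[:, 1])
    nrows, ncols = grid.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    valid = inside.copy()
    valid[inside] &= ~grid.nodata_mask[row[inside], col[inside]]
    kept = np.flatnonzero(valid)
    dropped = np.flatnonzero(~valid)
    reasons = ["outside extent" if not inside[i] else "nodata cell" for i in dropped]
    if kept.size == 0:
        raise ExtentError("no point falls on a valid cell")
    vals = grid.values[:, row[kept], col[kept]].T
    return ExtractionResult(vals, kept, dropped, reasons)


def sample_background(grid: EnvGrid, n: int = 10_000,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample ``n`` distinct valid cells uniformly without replacement.

    Returns an (n, 2) array of (lon, lat) cell-centre coordinates. The
    default of 10,000 points follows common presence-background practice.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    valid_flat = np.flatnonzero(~grid.nodata_mask.ravel())
    if n > valid_flat.size:
        raise CapacityError(
            f"requested {n} background points but only {valid_flat.size} valid cells")
    chosen = rng.choice(valid_flat, size=n, replace=False)
    row, col = np.unravel_index(chosen, grid.shape)
    lon, lat = grid.cell_center(row, col)
    return np.column_stack([lon, lat])


# ---------------------------------------------------------------------------
# Collinearity

def collinearity(matrix: pd.DataFrame | np.ndarray,
                 names: Sequence[str] | None = None) -> CollinearityReport:
    """Pairwise Pearson r / r² and per-variable VIF for a predictor matrix.

    ``VIF_j = 1 / (1 - R²_j)`` from regressing column j (with intercept) on
    all other columns. Perfectly collinear columns get ``inf``; constant
    columns get ``nan`` with a warning. Flags use the conventional
    r > 0.8, r² > 0.8, VIF > 10 thresholds.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = list(names) if names else [f"x{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if p < 2 or n < 3:
        raise ValueError("need at least 2 columns and 3 rows")
    constant = X.std(axis=0) == 0
    if constant.any():
        warnings.warn("constant column(s): correlation undefined, reported as nan",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    Xc = np.column_stack([np.ones(n), X])  # intercept for the auxiliary fits
    vif = np.empty(p)
    for j in range(p):
        if constant[j]:
            vif[j] = np.nan
            continue
        with np.errstate(divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = variance_inflation_factor(Xc, j + 1)
        # R²_j >= 1 within roundoff means exact linear dependence
        vif[j] = np.inf if (not np.isfinite(v) or v > 1e12) else max(v, 1.0)
    return CollinearityReport(names, r, vif=vif)
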