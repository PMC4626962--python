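"""Spatial machinery: IDW interpolation, natural-breaks classification,
and ESRI ASCII grid I/O.

Station-level values (concentrations, population densities, risk) are
spread onto a regular planar raster by inverse-distance weighting,

    v(cell) = sum_i w_i v_i / sum_i w_i,   w_i = d_i^(-power),

which interpolates exactly at station locations and is a convex
combination of the station values everywhere.  Raster values are
classified into risk tiers with Jenks natural breaks -- the exact
dynamic-programming partition of the sorted values minimizing the total
within-class sum of squared deviations.

All coordinates are planar (km); no geographic great-circle handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RasterField",
    "GridSpec",
    "grid_from_points",
    "idw_interpolate",
    "BreakSet",
    "jenks_breaks",
    "classify_raster",
]

NODATA = -9999.0


@dataclass
class GridSpec:
    """Geometry of a regular grid: lower-left corner, cell size, extent."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as 2D arrays; row 0 is the northernmost row."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (
            self.n_rows - np.arange(self.n_rows) - 0.5
        ) * self.cell_size
        return np.meshgrid(xs, ys)

    def __eq__(self, other):
        return isinstance(other, GridSpec) and (
            np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
            and self.n_cols == other.n_cols
            and self.n_rows == other.n_rows
        )


@dataclass
class RasterField:
    """Regular grid of values; ``values[0, :]`` is the northernmost row."""

    grid: GridSpec
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} != grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )

    def mask(self) -> np.ndarray:
        return self.values == self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask()]

    # -- ESRI ASCII grid I/O (6 significant digits, bit-stable formatting)

    def to_ascii(self, path) -> None:
        g = self.grid
        with open(path, "w") as fh:
            fh.write(f"ncols {g.n_cols}\n")
            fh.write(f"nrows {g.n_rows}\n")
            fh.write(f"xllcorner {g.origin_x:.6g}\n")
            fh.write(f"yllcorner {g.origin_y:.6g}\n")
            fh.write(f"cellsize {g.cell_size:.6g}\n")
            fh.write(f"NODATA_value {self.nodata:.6g}\n")
            for row in self.values:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_ascii(cls, path) -> "RasterField":
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                ):
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        grid = GridSpec(
            origin_x=header["xllcorner"],
            origin_y=header["yllcorner"],
            cell_size=header["cellsize"],
            n_cols=int(header["ncols"]),
            n_rows=int(header["nrows"]),
        )
        return cls(
            grid=grid,
            values=np.asarray(rows, dtype=float),
            nodata=header.get("nodata_value", NODATA),
        )


def grid_from_points(
    x: np.ndarray,
    y: np.ndarray,
    n_cols: int = 200,
    n_rows: int = 200,
    pad: float = 0.1,
) -> GridSpec:
    """Grid covering the bounding box of the points, padded by *pad*."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    span_x = max(x.max() - x.min(), 1e-6)
    span_y = max(y.max() - y.min(), 1e-6)
    x0 = x.min() - pad * span_x
    y0 = y.min() - pad * span_y
    width = span_x * (1 + 2 * pad)
    height = span_y * (1 + 2 * pad)
    cell = max(width / n_cols, height / n_rows)
    return GridSpec(x0, y0, cell, n_cols, n_rows)


def idw_interpolate(
    x: np.ndarray,
    y: np.ndarray,
    v: np.ndarray,
    grid: GridSpec,
    power: float = 2.0,
    k_nearest: int | None = None,
    eps: float = 1e-9,
) -> RasterField:
    """Inverse-distance-weighted interpolation onto *grid*.

    ``power`` is the (positive) distance exponent; ``k_nearest`` restricts
    the weighting to the k closest stations (default: all).  A cell whose
    center lies within *eps* km of a station takes that station's value
    exactly.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if len(x) == 0:
        raise ValueError("need at least one sample point")
    if not (len(x) == len(y) == len(v)):
        raise ValueError("x, y, v must have equal length")
    if power <= 0:
        raise ValueError("power must be > 0")

    gx, gy = grid.cell_centers()
    pts = np.column_stack([gx.ravel(), gy.ravel()])         # (C, 2)
    d = np.sqrt(
        (pts[:, 0, None] - x[None, :]) ** 2
        + (pts[:, 1, None] - y[None, :]) ** 2
    )                                                        # (C, S)
    if k_nearest is not None and k_nearest < len(x):
        kth = np.partition(d, k_nearest - 1, axis=1)[:, k_nearest - 1]
        far = d > kth[:, None]
    else:
        far = np.zeros_like(d, dtype=bool)

    exact = d < eps
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[far] = 0.0
    out = np.empty(len(pts))
    hit = exact.any(axis=1)
    if hit.any():
        out[hit] = v[exact.argmax(axis=1)[hit]]
    rest = ~hit
    out[rest] = (w[rest] @ v) / w[rest].sum(axis=1)
    return RasterField(grid, out.reshape(grid.n_rows, grid.n_cols))


# ---------------------------------------------------------------------------
# Jenks natural breaks


@dataclass
class BreakSet:
    """k classes over sorted values; ``breaks`` are the k-1 upper boundaries
    of the lower classes (intervals closed on the right)."""

    k: int
    breaks: list[float]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.breaks) != self.k - 1:
            raise ValueError("need exactly k-1 break values")
        if any(b >= c for b, c in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly ascending")
        if not self.labels:
            self.labels = (
                ["low", "moderate", "high"]
                if self.k == 3
                else [f"class_{i + 1}" for i in range(self.k)]
            )


def jenks_breaks(values: np.ndarray, k: int) -> BreakSet:
    """Exact natural-breaks classification by dynamic programming.

    Finds the partition of the sorted values into k contiguous classes
    minimizing the total within-class sum of squared deviations.  Requires
    at least k distinct values.  O(k n^2) with prefix sums.
    """
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    vals = vals[np.isfinite(vals)]
    n = len(vals)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(vals)) < k:
        raise ValueError(
            f"need at least k={k} distinct values, got {len(np.unique(vals))}"
        )

    c1 = np.concatenate([[0.0], np.cumsum(vals)])
    c2 = np.concatenate([[0.0], np.cumsum(vals * vals)])

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            # within-class SSD of vals[i..j-1] for all split points i at once
            i = np.arange(c - 1, j)
            s = c1[j] - c1[i]
            ssd = np.maximum(c2[j] - c2[i] - s * s / (j - i), 0.0)
            t = cost[c - 1, i] + ssd
            arg = int(np.argmin(t))
            cost[c, j] = t[arg]
            cut[c, j] = i[arg]

    # recover class boundaries (upper value of each class except the last)
    bounds = []
    j = n
    for c in range(k, 0, -1):
        i = cut[c, j]
        bounds.append((i, j))
        j = i
    bounds.reverse()
    breaks = [float(vals[j - 1]) for (_, j) in bounds[:-1]]
    bs = BreakSet(k=k, breaks=breaks)
    bs.objective = float(cost[k, n])  # total within-class SSD, for diagnostics
    return bs


def classify_raster(field: RasterField, breaks: BreakSet) -> RasterField:
    """Map each cell to a class index in [0, k); boundary values fall in the
    lower class (intervals closed on the right).  Nodata propagates."""
    v = field.values
    cls = np.searchsorted(np.asarray(breaks.breaks), v, side="left").astype(float)
    cls[field.mask()] = field.nodata
    return RasterField(field.grid, cls, nodata=field.nodata)
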