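"""File formats, grid geometry and DEM gridding.

Point surveys (ECa in mS/m, elevation in m) are delimited text with a
header; rasters are the ESRI ASCII grid dialect so every artifact in a run
directory is human-readable. Coordinates are planar metres in an already
projected system (e.g. ETRS89 / UTM); no CRS handling is attempted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

__all__ = [
    "PointSurvey",
    "RasterGrid",
    "read_point_survey",
    "clean_eca",
    "grid_elevation",
    "read_raster",
    "write_raster",
]


@dataclasses.dataclass
class PointSurvey:
    """Georeferenced scalar observations from a mobile survey.

    Attributes
    ----------
    x, y : ndarray
        Planar coordinates in metres (easting, northing).
    values : ndarray
        Observed variable: mS/m for ECa, m for elevation.
    variable_name : str
    depth_window : str
        Sensing depth label, e.g. ``"0-0.30 m"``.
    n_dropped : int
        Rows discarded while reading (unparseable or missing fields).
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    variable_name: str = "value"
    depth_window: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.x.shape == self.y.shape == self.values.shape):
            raise ValueError("x, y and values must have identical shapes")
        if self.x.size == 0:
            raise ValueError("a PointSurvey needs at least one record")
        if not (
            np.isfinite(self.x).all()
            and np.isfinite(self.y).all()
            and np.isfinite(self.values).all()
        ):
            raise ValueError("coordinates and values must all be finite")

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y)."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, self.variable_name: self.values}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def averaged_duplicates(self) -> "PointSurvey":
        """Average records sharing exact coordinates.

        Kriging and triangulation systems become singular with co-located
        points, so duplicates are collapsed to their mean value first.
        """
        df = self.to_frame()
        grouped = df.groupby(["x", "y"], as_index=False, sort=False).mean()
        if len(grouped) == len(df):
            return self
        return PointSurvey(
            grouped["x"].to_numpy(),
            grouped["y"].to_numpy(),
            grouped[self.variable_name].to_numpy(),
            variable_name=self.variable_name,
            depth_window=self.depth_window,
        )


@dataclasses.dataclass
class RasterGrid:
    """A regular grid of values with a simple geotransform.

    The origin is the lower-left corner of the lower-left cell; cells are
    square with side ``cell_size`` metres; ``values`` row 0 is the
    northernmost row (image convention, matching the ESRI ASCII layout).
    """

    x_origin: float
    y_origin: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def geometry(self) -> tuple[float, float, float, int, int]:
        return (self.x_origin, self.y_origin, self.cell_size,
                self.n_rows, self.n_cols)

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinates as (X, Y) 2-D arrays (row 0 = north)."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(self.n_rows)[::-1] + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.nodata))

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def like(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """A new raster on this geometry holding ``values``."""
        return RasterGrid(
            self.x_origin, self.y_origin, self.cell_size,
            np.asarray(values, dtype=float),
            self.nodata if nodata is None else nodata,
        )

    @classmethod
    def empty(cls, x_origin: float, y_origin: float, cell_size: float,
              n_rows: int, n_cols: int, nodata: float = -9999.0) -> "RasterGrid":
        return cls(x_origin, y_origin, cell_size,
                   np.full((n_rows, n_cols), np.nan), nodata)


def read_point_survey(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    variable_name: str = "value",
    depth_window: str = "",
) -> PointSurvey:
    """Read a delimited survey file into a :class:`PointSurvey`.

    ``column_map`` maps the logical names ``x``, ``y``, ``value`` to the
    file's column headers (default: identity for ``x``/``y`` and
    ``variable_name`` for the value). Rows where any mapped field is
    missing or unparseable are dropped and counted in ``n_dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = {"x": "x", "y": "y", "value": variable_name}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing mapped column(s) {missing} in {path.name}")
    sub = df[[cmap["x"], cmap["y"], cmap["value"]]].apply(
        pd.to_numeric, errors="coerce"
    )
    ok = sub.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    sub = sub[ok]
    if len(sub) == 0:
        raise ValueError(f"no valid rows in {path.name}")
    return PointSurvey(
        sub[cmap["x"]].to_numpy(),
        sub[cmap["y"]].to_numpy(),
        sub[cmap["value"]].to_numpy(),
        variable_name=variable_name,
        depth_window=depth_window,
        n_dropped=n_dropped,
    )


def clean_eca(
    survey: PointSurvey, min_value: float, max_value: float
) -> tuple[PointSurvey, int]:
    """Drop implausible readings (negative or excessively high values).

    Returns the cleaned survey and the number of records removed.
    """
    if min_value >= max_value:
        raise ValueError("min_value must be below max_value")
    keep = (survey.values >= min_value) & (survey.values <= max_value)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("cleaning removed every record")
    cleaned = PointSurvey(
        survey.x[keep], survey.y[keep], survey.values[keep],
        variable_name=survey.variable_name,
        depth_window=survey.depth_window,
    )
    return cleaned, n_removed


def grid_elevation(
    points: PointSurvey,
    template: RasterGrid,
    fill_outside: bool = False,
) -> RasterGrid:
    """Grid scattered elevation points onto a raster geometry.

    Piecewise-linear interpolation on the Delaunay triangulation of the
    points; cells outside the convex hull get nodata, or the
    nearest-neighbour value when ``fill_outside`` is set. Linear
    interpolation on a triangulation reproduces any affine surface
    exactly inside the hull.
    """
    pts = points.averaged_duplicates()
    if len(pts) < 3:
        raise ValueError("at least 3 non-collinear points are required")
    try:
        interp = LinearNDInterpolator(pts.coords, pts.values)
    except QhullError as exc:
        raise ValueError("points are collinear or degenerate") from exc
    gx, gy = template.cell_centers()
    z = interp(gx, gy)
    if fill_outside and np.isnan(z).any():
        nn = NearestNDInterpolator(pts.coords, pts.values)
        hole = np.isnan(z)
        z[hole] = nn(gx[hole], gy[hole])
    out = template.like(z)
    out.values[np.isnan(out.values)] = out.nodata
    return out


def write_raster(path: str | Path, grid: RasterGrid,
                 precision: int = 10) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    vals = grid.values.copy()
    vals[~grid.mask] = grid.nodata
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_origin!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=f"%.{precision}g")


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required.issubset(header):
        raise ValueError(f"malformed ESRI ASCII header in {path.name}")
    values = np.loadtxt(path, skiprows=n_header)
    values = np.atleast_2d(values)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"grid shape {values.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    return RasterGrid(
        header["xllcorner"], header["yllcorner"], header["cellsize"],
        values, header.get("nodata_value", -9999.0),
    )
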