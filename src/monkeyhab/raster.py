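"""Minimal single-band raster container with ESRI ASCII grid I/O.

North-up, square pixels, pixel-center registration. The ASCII grid
(``.asc``) format is used for on-disk exchange because it is plain text
and carries the full grid geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """A single-band raster.

    Attributes
    ----------
    data : ndarray (rows, cols)
        Cell values, row 0 is the northernmost row.
    x_origin, y_origin : float
        Coordinates of the *outer* top-left corner of the grid.
    pixel_size : float
        Cell edge length in map units (metres throughout this package).
    nodata : float
        Sentinel written to disk for missing cells; in-memory float
        rasters use NaN for missing.
    """

    data: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid outline."""
        rows, cols = self.shape
        return (
            self.x_origin,
            self.y_origin - rows * self.pixel_size,
            self.x_origin + cols * self.pixel_size,
            self.y_origin,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys) meshgrids of pixel-center coordinates."""
        rows, cols = self.shape
        xs = self.x_origin + (np.arange(cols) + 0.5) * self.pixel_size
        ys = self.y_origin - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices; no bounds clipping."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.pixel_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def like(self, data: np.ndarray) -> "Raster":
        """A new raster sharing this grid's geometry."""
        if np.shape(data) != self.shape:
            raise ValueError("shape mismatch with template grid")
        return replace(self, data=np.asarray(data))

    def same_grid(self, other: "Raster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid; NaN cells become the nodata value."""
    rows, cols = raster.shape
    data = np.asarray(raster.data, dtype=float)
    out = np.where(np.isnan(data), raster.nodata, data)
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {raster.x_origin!r}\n"
        f"yllcorner {raster.y_origin - rows * raster.pixel_size!r}\n"
        f"cellsize {raster.pixel_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:  # optional NODATA_value line absent
                fh.seek(pos)
                break
        data = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", -9999.0)
    rows = int(header["nrows"])
    cols = int(header["ncols"])
    if data.shape != (rows, cols):
        raise ValueError(f"grid body {data.shape} does not match header ({rows}, {cols})")
    data = np.where(data == nodata, np.nan, data)
    return Raster(
        data=data,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + rows * header["cellsize"],
        pixel_size=header["cellsize"],
        nodata=nodata,
    )
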