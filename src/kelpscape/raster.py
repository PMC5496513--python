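"""Minimal planar raster container with plain-text (ESRI ASCII grid) I/O.

All rasters in the package live in local projected meters.  The ESRI ASCII
``.asc`` format is used on disk: a plain-text header (ncols, nrows,
xllcorner, yllcorner, cellsize, NODATA_value) followed by rows of values
from the northern edge down.  Any GIS (GDAL, QGIS) reads it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from kelpscape.errors import ConfigError

NODATA = -9999.0


@dataclass
class Raster:
    """A single-band grid in planar meters.

    ``data[0, :]`` is the northernmost row; cell (row, col) has its center at
    ``(xmin + (col + 0.5) * resolution, ymax - (row + 0.5) * resolution)``.
    """

    xmin: float
    ymin: float
    resolution: float
    data: np.ndarray
    nodata: float = NODATA

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ConfigError("raster data must be a non-empty 2-D array")
        if self.resolution <= 0:
            raise ConfigError("raster resolution must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.resolution

    @property
    def ymax(self) -> float:
        return self.ymin + self.nrows * self.resolution

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshgrids of cell-center coordinates, shape = data.shape."""
        xs = self.xmin + (np.arange(self.ncols) + 0.5) * self.resolution
        ys = self.ymax - (np.arange(self.nrows) + 0.5) * self.resolution
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each planar point, clipped to
        the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.clip(((x - self.xmin) / self.resolution).astype(int), 0, self.ncols - 1)
        row = np.clip(((self.ymax - y) / self.resolution).astype(int), 0, self.nrows - 1)
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell values at planar points."""
        row, col = self.index_of(x, y)
        return self.data[row, col]

    def copy_with(self, data: np.ndarray) -> "Raster":
        if data.shape != self.data.shape:
            raise ConfigError("replacement grid shape mismatch")
        return Raster(self.xmin, self.ymin, self.resolution, np.asarray(data, float), self.nodata)

    # -- plain-text I/O -----------------------------------------------------

    def write_ascii(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xmin:.9g}\n")
            fh.write(f"yllcorner {self.ymin:.9g}\n")
            fh.write(f"cellsize {self.resolution:.9g}\n")
            fh.write(f"NODATA_value {self.nodata:.9g}\n")
            for row in self.data:
                fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        path = Path(path)
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with path.open() as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        data = np.array(rows, dtype=float)
        if data.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ConfigError(f"ASCII grid shape mismatch in {path}")
        return cls(
            xmin=header["xllcorner"],
            ymin=header["yllcorner"],
            resolution=header["cellsize"],
            data=data,
            nodata=header.get("nodata_value", NODATA),
        )


@dataclass
class EnvironmentRasters:
    """Aligned environmental grids: bathymetry (m, positive down) and a
    boolean rocky-reef mask."""

    bathymetry: Raster
    reef_mask: Raster = field(repr=False)

    def __post_init__(self):
        b, r = self.bathymetry, self.reef_mask
        if b.data.shape != r.data.shape or b.extent != r.extent:
            raise ConfigError("bathymetry and reef_mask grids are not aligned")

    @property
    def resolution(self) -> float:
        return self.bathymetry.resolution

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return self.bathymetry.extent

    def reef_bool(self) -> np.ndarray:
        return self.reef_mask.data > 0.5

    def write(self, directory, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.bathymetry.write_ascii(directory / f"{prefix}bathymetry.asc")
        self.reef_mask.write_ascii(directory / f"{prefix}reef_mask.asc")

    @classmethod
    def read(cls, directory, prefix: str = "") -> "EnvironmentRasters":
        directory = Path(directory)
        return cls(
            bathymetry=Raster.read_ascii(directory / f"{prefix}bathymetry.asc"),
            reef_mask=Raster.read_ascii(directory / f"{prefix}reef_mask.asc"),
        )
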