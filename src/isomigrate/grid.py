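"""Georeferenced single-band raster grids and isoscapes.

`GeoGrid` is the universal spatial carrier of the package: a 2-D float
array on a regular, north-up, square-cell grid, with NaN as the nodata
value.  Two coordinate conventions are supported through ``crs``:

* ``"cartesian"`` — an abstract equal-area plane; coordinates in km,
  planar distances.
* ``"geographic"`` — longitude/latitude in decimal degrees on a sphere;
  great-circle distances.

Rasters are serialized as ESRI ASCII grids (plain text), a format every
GIS reads.  An `Isoscape` is a (mean, SD) pair of grids for one isotope
system and is written as a pair of ``*_mean.asc`` / ``*_sd.asc`` files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

CARTESIAN = "cartesian"
GEOGRAPHIC = "geographic"


class OffGridError(ValueError):
    """A coordinate fell outside the grid extent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular north-up raster grid.

    ``(x0, y0)`` is the lower-left *corner* of the lower-left cell;
    ``cell`` is the (square) cell size in the units of the CRS (km for
    cartesian grids, degrees for geographic grids).  Row 0 of the value
    array is the northernmost row.
    """

    nrows: int
    ncols: int
    x0: float
    y0: float
    cell: float
    crs: str = CARTESIAN

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.crs not in (CARTESIAN, GEOGRAPHIC):
            raise ValueError(f"unknown crs {self.crs!r}")

    @property
    def x_max(self) -> float:
        return self.x0 + self.ncols * self.cell

    @property
    def y_max(self) -> float:
        return self.y0 + self.nrows * self.cell

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        """Row-centre y coordinates, row 0 (north) first."""
        return self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, shape (nrows, ncols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y)."""
        if not (self.x0 <= x <= self.x_max and self.y0 <= y <= self.y_max):
            raise OffGridError(f"point ({x}, {y}) outside grid extent")
        col = min(int((x - self.x0) / self.cell), self.ncols - 1)
        row_from_bottom = min(int((y - self.y0) / self.cell), self.nrows - 1)
        return self.nrows - 1 - row_from_bottom, col

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x_max and self.y0 <= y <= self.y_max


@dataclass
class GeoGrid:
    """A single-band raster: values on a `GridSpec`, NaN = nodata."""

    values: np.ndarray
    spec: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"{(self.spec.nrows, self.spec.ncols)}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    def like(self, values: np.ndarray) -> "GeoGrid":
        """New grid with the same geometry and different values."""
        return GeoGrid(np.asarray(values, dtype=float), self.spec)

    def value_at(self, x: float, y: float) -> float:
        r, c = self.spec.index_of(x, y)
        return float(self.values[r, c])

    def write_ascii(self, path: str | Path) -> None:
        spec = self.spec
        out = np.where(self.mask, self.values, -9999.0)
        header = (
            f"ncols {spec.ncols}\n"
            f"nrows {spec.nrows}\n"
            f"xllcorner {spec.x0!r}\n"
            f"yllcorner {spec.y0!r}\n"
            f"cellsize {spec.cell!r}\n"
            f"NODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path: str | Path, crs: str = CARTESIAN) -> "GeoGrid":
        with open(path) as fh:
            hdr: dict[str, float] = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        nodata = hdr.get("nodata_value", -9999.0)
        values[values == nodata] = np.nan
        spec = GridSpec(
            nrows=int(hdr["nrows"]),
            ncols=int(hdr["ncols"]),
            x0=hdr["xllcorner"],
            y0=hdr["yllcorner"],
            cell=hdr["cellsize"],
            crs=crs,
        )
        return cls(values, spec)


@dataclass
class Isoscape:
    """Paired mean and SD grids for one isotope system."""

    mean: GeoGrid
    sd: GeoGrid

    def __post_init__(self) -> None:
        if self.mean.spec != self.sd.spec:
            raise ValueError("mean and SD grids must share geometry")
        sd_vals = self.sd.values[self.sd.mask]
        if np.any(sd_vals < 0):
            raise ValueError("SD grid must be non-negative")

    @property
    def spec(self) -> GridSpec:
        return self.mean.spec

    def write(self, stem: str | Path) -> tuple[Path, Path]:
        """Write ``<stem>_mean.asc`` and ``<stem>_sd.asc``."""
        stem = Path(stem)
        mean_path = stem.with_name(stem.name + "_mean.asc")
        sd_path = stem.with_name(stem.name + "_sd.asc")
        self.mean.write_ascii(mean_path)
        self.sd.write_ascii(sd_path)
        return mean_path, sd_path

    @classmethod
    def read(cls, stem: str | Path, crs: str = CARTESIAN) -> "Isoscape":
        stem = Path(stem)
        mean = GeoGrid.read_ascii(stem.with_name(stem.name + "_mean.asc"), crs)
        sd = GeoGrid.read_ascii(stem.with_name(stem.name + "_sd.asc"), crs)
        return cls(mean, sd)


@dataclass
class PredictorStack:
    """Named collection of co-registered predictor layers."""

    layers: dict[str, GeoGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        specs = {g.spec for g in self.layers.values()}
        if len(specs) > 1:
            raise ValueError("all predictor layers must share grid geometry")
        for name, g in self.layers.items():
            if not g.mask.any():
                raise ValueError(f"layer {name!r} is all nodata")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def spec(self) -> GridSpec:
        if not self.layers:
            raise ValueError("empty predictor stack")
        return next(iter(self.layers.values())).spec

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> GeoGrid:
        return self.layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def subset(self, names: Sequence[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"missing predictor layer(s): {missing}")
        return PredictorStack({n: self.layers[n] for n in names})

    def add(self, name: str, grid: GeoGrid) -> None:
        if self.layers and grid.spec != self.spec:
            raise ValueError("layer geometry does not match stack")
        self.layers[name] = grid

    def valid_mask(self) -> np.ndarray:
        """Cells where every layer holds data."""
        m = np.ones((self.spec.nrows, self.spec.ncols), dtype=bool)
        for g in self.layers.values():
            m &= g.mask
        return m

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, GeoGrid]) -> "PredictorStack":
        return cls(dict(mapping))
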