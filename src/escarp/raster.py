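"""Categorical land-use rasters and minimal georeferenced TIFF I/O.

A :class:`LandUseRaster` is a rectangular integer lattice of land-cover
class codes (1..6) with a nodata sentinel, a cell edge length in meters,
and an opaque georeference (origin + CRS tag) that is carried through
I/O untouched.  Rasters are written as plain TIFF with a JSON sidecar
(`<name>.tif` + `<name>.tif.json`) holding the georeference, so the
round trip needs no GDAL stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

#: valid land-cover class codes
CLASS_CODES = (1, 2, 3, 4, 5, 6)
#: default nodata sentinel
NODATA = 0


@dataclass
class LandUseRaster:
    """Categorical land-cover grid.

    Parameters
    ----------
    values : ndarray of int, shape (nrows, ncols)
        Class codes in ``{1..6}`` plus the nodata sentinel.
    cell_size_m : float
        Cell edge length in meters (> 0).
    origin : tuple of float
        (x, y) of the upper-left corner; opaque, carried through I/O.
    crs : str
        Coordinate-reference-system tag; opaque, carried through I/O.
    nodata : int
        Sentinel marking cells outside the analysis area.
    """

    values: np.ndarray
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "local"
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("raster values must be integers (class codes)")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        valid = set(CLASS_CODES) | {self.nodata}
        present = set(np.unique(self.values).tolist())
        if not present <= valid:
            raise ValueError(
                f"invalid class codes {sorted(present - valid)}; "
                f"expected subset of {sorted(valid)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2

    def data_mask(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return self.values != self.nodata


def write_raster(raster: LandUseRaster | np.ndarray, path: str | Path,
                 cell_size_m: float | None = None, **meta) -> None:
    """Write a raster as TIFF plus a JSON georeference sidecar."""
    path = Path(path)
    if isinstance(raster, LandUseRaster):
        values = raster.values
        sidecar = {
            "cell_size_m": raster.cell_size_m,
            "origin": list(raster.origin),
            "crs": raster.crs,
            "nodata": int(raster.nodata),
        }
    else:
        values = np.asarray(raster)
        sidecar = {"cell_size_m": cell_size_m, **meta}
    tifffile.imwrite(path, values)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )


def read_landuse(path: str | Path) -> LandUseRaster:
    """Read a land-use TIFF written by :func:`write_raster`."""
    path = Path(path)
    values = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return LandUseRaster(
        values=np.asarray(values),
        cell_size_m=float(meta["cell_size_m"]),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        crs=meta.get("crs", "local"),
        nodata=int(meta.get("nodata", NODATA)),
    )


def read_surface(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a continuous surface TIFF (NDVI, population, supply) + metadata."""
    path = Path(path)
    values = np.asarray(tifffile.imread(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return values, meta
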