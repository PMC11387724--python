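"""Light-environment niche overlap from suitability rasters.

Species' habitat-suitability surfaces (e.g. ecological-niche-model output)
and NDVI layers are plain gridded rasters.  Overlap between two species is
Schoener's D,

    D = 1 - 1/2 * sum_i |p_i - q_i|,

with p and q the cell-wise suitability surfaces of the two species, each
normalized to sum to one.  D ranges from 0 (disjoint niches) to 1
(identical niches) and equals one minus the total-variation distance
between the two normalized surfaces.

Rasters are read and written in the ESRI ASCII grid dialect (ncols/nrows/
xllcorner/yllcorner/cellsize header followed by rows of values).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import shapely

from .geography import RangePolygon


class NicheError(ValueError):
    pass


@dataclass
class SuitabilityRaster:
    """Rectangular grid of non-negative suitability (or NDVI) values.

    Row 0 is the northernmost row, following the ASCII grid convention;
    ``xll``/``yll`` locate the lower-left corner of the grid.
    """

    values: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise NicheError("raster values must be a 2-D array")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise NicheError("raster values must be finite and non-negative")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "SuitabilityRaster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of cell centres, same shape as values."""
        nrows, ncols = self.shape
        xs = self.xll + (np.arange(ncols) + 0.5) * self.cellsize
        ys = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)


@dataclass
class NicheOverlap:
    species1: str
    species2: str
    D: float
    variable_set: str = "all"  # "NDVI" | "all"


def normalize_surface(raster: SuitabilityRaster) -> SuitabilityRaster:
    """Divide cells by their sum so the surface is a probability distribution."""
    total = raster.values.sum()
    if total <= 0:
        raise NicheError(f"raster {raster.name!r} is all zero; cannot normalize")
    return replace(raster, values=raster.values / total)


def schoeners_D(
    r1: SuitabilityRaster, r2: SuitabilityRaster, variable_set: str = "all"
) -> NicheOverlap:
    """Schoener's D niche overlap between two rasters on one shared grid."""
    if not r1.same_grid(r2):
        raise NicheError("rasters are on mismatched grids")
    p = normalize_surface(r1).values
    q = normalize_surface(r2).values
    d = 1.0 - 0.5 * np.abs(p - q).sum()
    return NicheOverlap(r1.name, r2.name, float(np.clip(d, 0.0, 1.0)), variable_set)


def mean_ndvi(
    ndvi: SuitabilityRaster,
    range_polygon: RangePolygon | None = None,
    suitability: SuitabilityRaster | None = None,
) -> float:
    """Species-level mean NDVI over its occupied habitat.

    Range mode: unweighted mean over cells whose centres fall strictly inside
    the range polygon (boundary ties excluded).  Raster mode: suitability-
    weighted mean sum(p_i * NDVI_i) with p the normalized suitability.
    """
    if (range_polygon is None) == (suitability is None):
        raise NicheError("provide exactly one of range_polygon or suitability")
    if range_polygon is not None:
        xs, ys = ndvi.cell_centres()
        inside = shapely.contains_xy(range_polygon.geometry, xs.ravel(), ys.ravel())
        if not inside.any():
            raise NicheError(f"range of {range_polygon.species!r} covers no cell centres")
        return float(ndvi.values.ravel()[inside].mean())
    if not ndvi.same_grid(suitability):
        raise NicheError("NDVI and suitability rasters are on mismatched grids")
    p = normalize_surface(suitability).values
    return float((p * ndvi.values).sum())


def read_ascii_grid(path: str | Path, name: str = "") -> SuitabilityRaster:
    """Read an ESRI ASCII grid (ncols/nrows/xll/yll/cellsize header + rows)."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        tokens = lines[i].split()
        if len(tokens) == 2 and tokens[0].lower().lstrip("-").replace(".", "").isalpha():
            header[tokens[0].lower()] = float(tokens[1])
            i += 1
        else:
            break
    required = {"ncols", "nrows", "cellsize"}
    if not required <= header.keys():
        raise NicheError(f"{path}: ASCII grid header missing {required - header.keys()}")
    values = np.loadtxt(lines[i:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise NicheError(f"{path}: grid body shape {values.shape} disagrees with header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, 0.0, values)
    return SuitabilityRaster(
        values,
        xll=header.get("xllcorner", header.get("xll", 0.0)),
        yll=header.get("yllcorner", header.get("yll", 0.0)),
        cellsize=header["cellsize"],
        name=name or Path(path).stem,
    )


def write_ascii_grid(raster: SuitabilityRaster, path: str | Path) -> None:
    nrows, ncols = raster.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {raster.xll:.8g}\nyllcorner {raster.yll:.8g}\n"
        f"cellsize {raster.cellsize:.8g}\n"
    )
    body = "\n".join(" ".join(f"{v:.8g}" for v in row) for row in raster.values)
    Path(path).write_text(header + body + "\n")
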