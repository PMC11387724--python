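"""Species range geometry: minimal distances, overlap fractions, sympatry.

Ranges are simple polygons (possibly multi-part) in either planar
coordinates (arbitrary units) or lon/lat degrees.  In planar mode distances
are Euclidean; in geodesic mode they are great-circle distances on a
spherical Earth (R = 6371 km), evaluated over densified polygon boundaries.

Sympatry follows a single consistent rule: a pair is sympatric iff the
intersection of their ranges has positive area.  Boundary-touching ranges
(zero distance but zero-area intersection) are classified allopatric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

EARTH_RADIUS_KM = 6371.0


class GeographyError(ValueError):
    pass


@dataclass
class RangePolygon:
    """A species' distributional range: union of one or more simple polygons."""

    species: str
    geometry: Polygon | MultiPolygon
    mode: str = "planar"  # "planar" | "lonlat"

    def __post_init__(self) -> None:
        if self.mode not in ("planar", "lonlat"):
            raise GeographyError(f"unknown coordinate mode {self.mode!r}")
        if not self.geometry.is_valid:
            raise GeographyError(f"range of {self.species!r} is not a valid polygon")
        if self.geometry.area <= 0:
            raise GeographyError(f"range of {self.species!r} has zero area")

    @classmethod
    def from_parts(
        cls, species: str, parts: list[list[tuple[float, float]]], mode: str = "planar"
    ) -> "RangePolygon":
        polys = [Polygon(p) for p in parts]
        return cls(species, unary_union(polys), mode)

    @property
    def area(self) -> float:
        return self.geometry.area


@dataclass
class PairGeoMetrics:
    """Geographic metrics for one unordered species pair."""

    species1: str
    species2: str
    min_distance: float
    intersection_area: float
    overlap_frac_1: float  #: intersection / area(species1)
    overlap_frac_2: float  #: intersection / area(species2)
    sympatric: bool


def _densify_boundary(geom: Polygon | MultiPolygon, max_seg: float) -> np.ndarray:
    """Boundary vertices with extra points so no segment exceeds ``max_seg``."""
    pts = []
    polys = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    for poly in polys:
        rings = [poly.exterior, *poly.interiors]
        for ring in rings:
            xy = np.asarray(ring.coords)
            for k in range(len(xy) - 1):
                a, b = xy[k], xy[k + 1]
                seg = np.hypot(*(b - a))
                n = max(1, int(np.ceil(seg / max_seg)))
                t = np.linspace(0, 1, n, endpoint=False)
                pts.append(a + t[:, None] * (b - a))
    return np.vstack(pts)


def _haversine_min(p1: np.ndarray, p2: np.ndarray) -> float:
    """Min great-circle distance (km) between two point sets in lon/lat degrees."""
    lon1, lat1 = np.radians(p1[:, 0])[:, None], np.radians(p1[:, 1])[:, None]
    lon2, lat2 = np.radians(p2[:, 0])[None, :], np.radians(p2[:, 1])[None, :]
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(h, 0, 1))).min())


def min_range_distance(r1: RangePolygon, r2: RangePolygon) -> float:
    """Minimal boundary-to-boundary distance; 0 when the ranges intersect.

    Planar mode is exact (shapely).  Geodesic mode samples the boundaries at
    ~0.05 degree resolution and minimizes the haversine distance.
    """
    if r1.mode != r2.mode:
        raise GeographyError("ranges are in mixed coordinate modes")
    if r1.geometry.intersects(r2.geometry):
        return 0.0
    if r1.mode == "planar":
        return float(r1.geometry.distance(r2.geometry))
    b1 = _densify_boundary(r1.geometry, 0.05)
    b2 = _densify_boundary(r2.geometry, 0.05)
    return _haversine_min(b1, b2)


def overlap_fractions(r1: RangePolygon, r2: RangePolygon) -> tuple[float, float, float]:
    """(intersection_area, intersection/area1, intersection/area2)."""
    if r1.area <= 0 or r2.area <= 0:
        raise GeographyError("zero-area input range")
    inter = r1.geometry.intersection(r2.geometry).area
    return float(inter), float(inter / r1.area), float(inter / r2.area)


def classify_sympatry(metrics: PairGeoMetrics) -> bool:
    """Sympatric iff the range intersection has positive area."""
    return metrics.intersection_area > 0


def pair_geo_metrics(r1: RangePolygon, r2: RangePolygon) -> PairGeoMetrics:
    inter, f1, f2 = overlap_fractions(r1, r2)
    dist = min_range_distance(r1, r2)
    sympatric = inter > 0
    if sympatric:
        dist = 0.0
    return PairGeoMetrics(r1.species, r2.species, dist, inter, f1, f2, sympatric)


def pairwise_geo_table(ranges: list[RangePolygon]) -> list[PairGeoMetrics]:
    """Full metrics for every unordered species pair (lexicographic order)."""
    ids = [r.species for r in ranges]
    if len(set(ids)) != len(ids):
        raise GeographyError("duplicate species ids in range list")
    if len(ranges) < 2:
        raise GeographyError("need at least two species")
    by_id = {r.species: r for r in ranges}
    return [
        pair_geo_metrics(by_id[a], by_id[b])
        for a, b in itertools.combinations(sorted(ids), 2)
    ]


def read_ranges(path: str | Path, mode: str = "planar") -> list[RangePolygon]:
    """Read ranges from the plain polygon text format.

    A non-numeric line starts a new species (its id); subsequent ``x y``
    lines are vertices; a blank line separates parts of a multi-part range.
    """
    ranges: list[RangePolygon] = []
    species: str | None = None
    parts: list[list[tuple[float, float]]] = []
    current: list[tuple[float, float]] = []

    def flush_part() -> None:
        nonlocal current
        if current:
            parts.append(current)
            current = []

    def flush_species() -> None:
        nonlocal parts
        flush_part()
        if species is not None:
            if not parts:
                raise GeographyError(f"species {species!r} has no vertices")
            ranges.append(RangePolygon.from_parts(species, parts, mode))
        parts = []

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            flush_part()
            continue
        tokens = line.split()
        try:
            x, y = float(tokens[0]), float(tokens[1])
        except (ValueError, IndexError):
            flush_species()
            species = line
            continue
        current.append((x, y))
    flush_species()
    if not ranges:
        raise GeographyError(f"{path} contains no ranges")
    return ranges


def write_ranges(ranges: list[RangePolygon], path: str | Path) -> None:
    lines: list[str] = []
    for r in ranges:
        lines.append(r.species)
        polys = r.geometry.geoms if isinstance(r.geometry, MultiPolygon) else [r.geometry]
        for k, poly in enumerate(polys):
            if k:
                lines.append("")
            lines.extend(f"{x:.8g} {y:.8g}" for x, y in poly.exterior.coords[:-1])
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")
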