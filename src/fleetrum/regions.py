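"""Spatial partition of the fishing area and great-circle geometry.

The eastern Pacific purse-seine fishery operates over roughly 10^6 km^2,
from the American coast out to about 150W.  Decision alternatives in the
choice models are not individual 1x1-degree cells but a small number of
labeled regions; this module holds that partition (R regions, default 12),
assigns positions to regions, and computes the great-circle distances that
proxy travel cost.

Region geometry is an input: the partition used with real observer data is
not published, so the packaged default (:func:`default_region_set`) is an
approximate rectangular 4x3 split of the EPO box, explicitly configurable
via GeoJSON (:func:`load_region_set`).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry

#: IUGG mean Earth radius, km.  Haversine on a sphere is used throughout:
#: distances are a km-scale cost proxy, not navigation output.
EARTH_RADIUS_KM = 6371.0088


class RegionValidationError(ValueError):
    """Raised when a region file violates the partition contract."""


@dataclass(frozen=True)
class GeoPoint:
    """A longitude/latitude position in decimal degrees (WGS84, lon east)."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError(f"non-finite coordinates ({self.lon}, {self.lat})")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class Region:
    """One labeled decision region: id, polygon, and its midpoint."""

    region_id: int
    polygon: BaseGeometry
    midpoint: GeoPoint


@dataclass
class RegionSet:
    """An ordered partition of the study area into R labeled regions.

    Invariants (enforced by :meth:`validate`):

    * region ids are 1..R, consecutive and unique;
    * polygon interiors are pairwise disjoint (shared boundaries allowed);
    * each region's midpoint lies inside (or on the boundary of) its own
      polygon.
    """

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: r.region_id)
        self.validate()

    @property
    def R(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> list[int]:
        return [r.region_id for r in self.regions]

    def __getitem__(self, region_id: int) -> Region:
        try:
            return self.regions[self.region_ids.index(region_id)]
        except ValueError:
            raise KeyError(f"no region with id {region_id}") from None

    def midpoints(self) -> np.ndarray:
        """(R, 2) array of midpoint (lon, lat) in region order."""
        return np.array([[r.midpoint.lon, r.midpoint.lat] for r in self.regions])

    def bounds(self) -> tuple[float, float, float, float]:
        """(lonmin, latmin, lonmax, latmax) of the union of polygons."""
        b = np.array([r.polygon.bounds for r in self.regions])
        return (b[:, 0].min(), b[:, 1].min(), b[:, 2].max(), b[:, 3].max())

    def validate(self) -> None:
        ids = self.region_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RegionValidationError(f"duplicate region ids {dupes}")
        if ids != list(range(1, len(ids) + 1)):
            raise RegionValidationError(
                f"region ids must be consecutive 1..R, got {ids}"
            )
        for r in self.regions:
            if not r.polygon.is_valid or r.polygon.is_empty:
                raise RegionValidationError(f"region {r.region_id}: invalid polygon")
            if not r.polygon.covers(Point(r.midpoint.lon, r.midpoint.lat)):
                raise RegionValidationError(
                    f"region {r.region_id}: midpoint outside its polygon"
                )
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1 :]:
                inter = a.polygon.intersection(b.polygon)
                if inter.area > 1e-9:
                    raise RegionValidationError(
                        f"regions {a.region_id} and {b.region_id} overlap "
                        f"(area {inter.area:.3g} deg^2)"
                    )

    def to_geojson(self) -> dict:
        feats = []
        for r in self.regions:
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"region_id": r.region_id},
                    "geometry": mapping(r.polygon),
                }
            )
        return {"type": "FeatureCollection", "features": feats}


def _snapped_midpoint(poly: BaseGeometry) -> GeoPoint:
    """Vertex-centroid of the polygon, snapped inside if it falls outside."""
    c = poly.centroid
    if not poly.covers(c):
        c = poly.representative_point()
    return GeoPoint(lon=float(c.x), lat=float(c.y))


def region_set_from_polygons(
    polygons: Sequence[tuple[int, BaseGeometry]],
) -> RegionSet:
    regions = [
        Region(region_id=int(rid), polygon=poly, midpoint=_snapped_midpoint(poly))
        for rid, poly in polygons
    ]
    return RegionSet(regions=regions)


def assign_region(p: GeoPoint, rs: RegionSet) -> Optional[int]:
    """Region id containing ``p``, or None outside the partition.

    Points on a boundary shared by several regions resolve to the lowest
    region id (regions are scanned in id order), keeping the assignment a
    deterministic function of position.
    """
    if not isinstance(p, GeoPoint):
        p = GeoPoint(*p)
    pt = Point(p.lon, p.lat)
    for r in rs.regions:  # sorted by id: lowest id wins boundary ties
        if r.polygon.covers(pt):
            return r.region_id
    return None


def geodesic_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle (haversine) distance in km on the IUGG mean sphere."""
    if not isinstance(a, GeoPoint):
        a = GeoPoint(*a)
    if not isinstance(b, GeoPoint):
        b = GeoPoint(*b)
    la1, la2 = math.radians(a.lat), math.radians(b.lat)
    dlat = la2 - la1
    dlon = math.radians(b.lon - a.lon)
    h = math.sin(dlat / 2.0) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geodesic_km_vec(lon: np.ndarray, lat: np.ndarray, p: GeoPoint) -> np.ndarray:
    """Vectorized haversine from arrays of (lon, lat) to a single point."""
    la1 = np.radians(np.asarray(lat, dtype=float))
    la2 = math.radians(p.lat)
    dlat = la2 - la1
    dlon = np.radians(p.lon - np.asarray(lon, dtype=float))
    h = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * math.cos(la2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def expected_distances(p: GeoPoint, rs: RegionSet) -> np.ndarray:
    """Distance (km) from ``p`` to each region midpoint, in region order.

    This is the "expected distance" cost proxy: from the home port (first
    choice of a trip) or the current position (switching choices) to the
    midpoint of each candidate region.
    """
    mids = rs.midpoints()
    return geodesic_km_vec(mids[:, 0], mids[:, 1], p)


def arrival_distances(rs: RegionSet, arrival_port: GeoPoint) -> np.ndarray:
    """Distance (km) from each region midpoint to the arrival port.

    By symmetry of the great-circle metric this equals
    ``expected_distances(arrival_port, rs)``; kept as a named operation
    because it plays a distinct economic role (cost of returning to unload).
    """
    return expected_distances(arrival_port, rs)


def load_region_set(source: Union[str, dict]) -> RegionSet:
    """Load and validate a RegionSet from a GeoJSON FeatureCollection.

    Each Feature must carry an integer ``region_id`` property; coordinates
    are decimal-degree lon/lat.  ``source`` may be a path or an
    already-parsed GeoJSON dict.
    """
    if isinstance(source, dict):
        gj = source
    else:
        with open(source) as fh:
            gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise RegionValidationError("expected a GeoJSON FeatureCollection")
    polys = []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "region_id" not in props:
            raise RegionValidationError("feature missing 'region_id' property")
        polys.append((int(props["region_id"]), shape(feat["geometry"])))
    ids = [rid for rid, _ in polys]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise RegionValidationError(f"duplicate region ids {dupes}")
    return region_set_from_polygons(polys)


def default_region_set() -> RegionSet:
    """The packaged approximate 12-region EPO partition.

    A 4 (longitude) x 3 (latitude) rectangular grid over 150W-75W,
    25S-35N, numbered row-major from the northwest.  The real partition
    used with observer data follows oceanography and fleet operations and
    is not published; any GeoJSON partition can be substituted.
    """
    with resources.files("fleetrum.data").joinpath("epo_regions.geojson").open() as fh:
        return load_region_set(json.load(fh))


def load_ports(source: Union[str, None] = None) -> dict[str, GeoPoint]:
    """Port registry: name -> GeoPoint.

    CSV columns: port_name, lon, lat, country (ISO-3166 alpha-3).  With no
    argument, returns the packaged default ports.
    """
    if source is None:
        ctx = resources.files("fleetrum.data").joinpath("ports.csv").open()
    else:
        ctx = open(source)
    ports: dict[str, GeoPoint] = {}
    with ctx as fh:
        for row in csv.DictReader(fh):
            ports[row["port_name"]] = GeoPoint(float(row["lon"]), float(row["lat"]))
    return ports


def snap_to_cell_center(p: GeoPoint) -> GeoPoint:
    """Snap a position to the center of its 1x1-degree cell.

    Observer event logs are aggregated to one-degree cells; cell centers
    sit at integer + 0.5 degrees.
    """
    return GeoPoint(math.floor(p.lon) + 0.5, math.floor(p.lat) + 0.5)


def region_cells(rs: RegionSet) -> dict[int, list[tuple[float, float]]]:
    """1x1-degree cell centers of each region, keyed by region id.

    Cell membership follows the same boundary tie rule as
    :func:`assign_region` (lowest id wins), so the per-region cell lists
    partition the gridded study area.
    """
    lonmin, latmin, lonmax, latmax = rs.bounds()
    out: dict[int, list[tuple[float, float]]] = {rid: [] for rid in rs.region_ids}
    lon0, lat0 = math.floor(lonmin), math.floor(latmin)
    for i in range(int(math.ceil(lonmax - lon0))):
        for j in range(int(math.ceil(latmax - lat0))):
            c = GeoPoint(lon0 + i + 0.5, lat0 + j + 0.5)
            rid = assign_region(c, rs)
            if rid is not None:
                out[rid].append((c.lon, c.lat))
    return out
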