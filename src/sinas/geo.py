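"""Location reference system and range-map overlay.

A run's geography is defined by two inputs: a polygon layer (GeoJSON, one
feature per standardized location, WGS84 lon/lat) and a location
translation table (delimited text) carrying, per location, its stable
``locationID``, alternative names and spellings, the subdivisions
(states/provinces) that up-scale to it, and one column per regional
aggregation scheme. Location geometries must be pairwise non-overlapping
up to boundary contact, so that the overlay of a range map onto the layer
partitions the range among locations.

Range maps (polygon features with per-feature origin codes) are converted
to checklist records by intersecting each feature with every location and
keeping positive-area overlaps only — boundary contact alone never yields
a presence. An optional minimum covered-area fraction guards against
slivers from coarse range maps overhanging borders.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from sinas._text import normalize
from sinas.data_model import RawRecord

logger = logging.getLogger(__name__)

LIST_SEP = "|"  # separator inside alternatives/subdivisions cells
_EARTH_RADIUS_KM = 6371.0


class LocationLoadError(ValueError):
    pass


class AmbiguousLocationError(ValueError):
    """One verbatim name resolves to two different locations: a defect of
    the translation table, not of the data."""


@dataclass
class Location:
    name: str
    location_id: int
    alternatives: set[str] = field(default_factory=set)
    subdivisions: set[str] = field(default_factory=set)
    region_memberships: dict[str, str] = field(default_factory=dict)
    geometry: BaseGeometry | None = None

    def __post_init__(self) -> None:
        self.alternatives.add(self.name)  # self-match always succeeds


@dataclass
class RangeFeature:
    taxon_verbatim: str
    geometry: BaseGeometry
    origin_code: str
    source_name: str


@dataclass
class Unmatched:
    """Marker for a verbatim location name with no translation."""

    verbatim: str


class LocationIndex:
    """Normalized-name lookup over a set of locations.

    Match order: standardized names and alternatives first, then
    subdivisions (up-scaling). Collisions within a tier are recorded and
    raised only when the ambiguous name is actually queried.
    """

    def __init__(self, locations: list[Location]):
        self.locations = locations
        self.by_id = {loc.location_id: loc for loc in locations}
        self._names: dict[str, Location] = {}
        self._subdivisions: dict[str, Location] = {}
        self._ambiguous: dict[str, set[str]] = {}
        for loc in locations:
            for alt in loc.alternatives:
                self._put(self._names, normalize(alt), loc)
            for sub in loc.subdivisions:
                self._put(self._subdivisions, normalize(sub), loc)

    def _put(self, table: dict[str, Location], key: str, loc: Location) -> None:
        other = table.get(key)
        if other is not None and other.name != loc.name:
            self._ambiguous.setdefault(key, set()).update({other.name, loc.name})
        else:
            table[key] = loc

    def lookup(self, verbatim: str) -> Location | Unmatched:
        key = normalize(verbatim)
        if key in self._ambiguous:
            raise AmbiguousLocationError(
                f"'{verbatim}' matches multiple locations: {sorted(self._ambiguous[key])}"
            )
        if key in self._names:
            return self._names[key]
        if key in self._subdivisions:
            return self._subdivisions[key]
        return Unmatched(verbatim)

    def __iter__(self):
        return iter(self.locations)

    def __len__(self) -> int:
        return len(self.locations)


def _split_cell(cell: str) -> set[str]:
    return {part.strip() for part in str(cell).split(LIST_SEP) if part.strip()}


def _equal_area(geom: BaseGeometry) -> BaseGeometry:
    """Lambert cylindrical equal-area transform for area thresholds (km^2)."""

    def _project(coords: np.ndarray) -> np.ndarray:
        lon = np.radians(coords[:, 0]) * _EARTH_RADIUS_KM
        lat = np.sin(np.radians(coords[:, 1])) * _EARTH_RADIUS_KM
        return np.column_stack([lon, lat])

    return shapely.transform(geom, _project)


def load_locations(
    polygon_path: str | Path,
    translation_path: str | Path,
    overlap_tolerance_km2: float = 1e-6,
) -> LocationIndex:
    """Join the polygon layer to the translation table.

    Every polygon feature must carry a ``location`` property present in the
    translation table; orphans on either side are a load error. Pairwise
    interior overlap above ``overlap_tolerance_km2`` is a geometry error
    naming the offending pair (boundary contact is allowed).
    """
    table = pd.read_csv(translation_path, dtype=str, keep_default_na=False)
    required = {"location", "locationID"}
    if missing := required - set(table.columns):
        raise LocationLoadError(f"translation table missing columns: {sorted(missing)}")
    scheme_cols = [
        c for c in table.columns if c not in {"location", "locationID", "alternatives", "subdivisions"}
    ]

    ids = table["locationID"].astype(int)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique().tolist())
        raise LocationLoadError(f"duplicate locationID in translation table: {dupes}")

    locations: dict[str, Location] = {}
    for _, row in table.iterrows():
        loc = Location(
            name=row["location"],
            location_id=int(row["locationID"]),
            alternatives=_split_cell(row.get("alternatives", "")),
            subdivisions=_split_cell(row.get("subdivisions", "")),
            region_memberships={s: row[s] for s in scheme_cols if str(row[s]).strip()},
        )
        locations[loc.name] = loc

    with open(polygon_path, encoding="utf-8") as fh:
        layer = json.load(fh)
    orphans = []
    for feat in layer.get("features", []):
        name = feat.get("properties", {}).get("location")
        if name not in locations:
            orphans.append(name)
            continue
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
        locations[name].geometry = geom
    if orphans:
        raise LocationLoadError(f"polygon features with no translation-table row: {orphans}")

    with_geom = [loc for loc in locations.values() if loc.geometry is not None]
    for i, a in enumerate(with_geom):
        for b in with_geom[i + 1 :]:
            if not a.geometry.intersects(b.geometry):
                continue
            inter = a.geometry.intersection(b.geometry)
            if _equal_area(inter).area > overlap_tolerance_km2:
                raise LocationLoadError(
                    f"locations '{a.name}' and '{b.name}' overlap beyond tolerance"
                )
    return LocationIndex(list(locations.values()))


def standardize_location(verbatim: str, locations: LocationIndex) -> Location | Unmatched:
    """Resolve a verbatim location name to a standardized Location.

    Names and alternative spellings match directly; subdivision names
    up-scale to their parent location; anything else returns an
    :class:`Unmatched` marker carrying the verbatim text.
    """
    return locations.lookup(verbatim)


def load_range_features(path: str | Path, source_name: str) -> list[RangeFeature]:
    """Read a range-map layer (GeoJSON) into features.

    Expected feature properties: ``taxon`` and ``origin`` (presence/origin
    code such as native, reintroduced, introduced, vagrant). Geometries
    that stay invalid after repair are skipped and logged.
    """
    with open(path, encoding="utf-8") as fh:
        layer = json.load(fh)
    features: list[RangeFeature] = []
    for feat in layer.get("features", []):
        props = feat.get("properties", {})
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
        if not geom.is_valid or geom.is_empty:
            logger.warning("skipping unrepairable geometry for taxon %s", props.get("taxon"))
            continue
        features.append(
            RangeFeature(
                taxon_verbatim=props.get("taxon", ""),
                geometry=geom,
                origin_code=props.get("origin", ""),
                source_name=source_name,
            )
        )
    return features


def overlay_range_maps(
    features: list[RangeFeature],
    locations: LocationIndex,
    origin_keep: set[str],
    min_area_fraction: float = 0.0,
) -> list[RawRecord]:
    """Convert range-map polygons into per-location checklist records.

    Features whose origin code is not in ``origin_keep`` are discarded.
    Each surviving feature yields one record per location it overlaps with
    positive area; boundary contact alone is never a presence. With
    ``min_area_fraction`` > 0 a location counts only when the feature
    covers at least that fraction of the location's (equal-area) extent.
    Duplicate (taxon, location) pairs are collapsed, keeping the first.
    """
    if not origin_keep:
        raise ValueError("origin_keep must be non-empty")
    keep_norm = {normalize(code) for code in origin_keep}
    records: list[RawRecord] = []
    seen: set[tuple[str, int]] = set()
    for feat in features:
        if normalize(feat.origin_code) not in keep_norm:
            continue
        for loc in locations:
            if loc.geometry is None or not feat.geometry.intersects(loc.geometry):
                continue
            inter = feat.geometry.intersection(loc.geometry)
            if inter.is_empty or inter.area <= 0:
                continue  # boundary touch only
            if min_area_fraction > 0:
                frac = _equal_area(inter).area / _equal_area(loc.geometry).area
                if frac < min_area_fraction:
                    continue
            key = (feat.taxon_verbatim, loc.location_id)
            if key in seen:
                continue
            seen.add(key)
            records.append(
                RawRecord(
                    source_name=feat.source_name,
                    taxon_verbatim=feat.taxon_verbatim,
                    location_verbatim=loc.name,
                    establishment_verbatim=feat.origin_code,
                )
            )
    return records


def aggregate_region(location: Location, scheme: str) -> str:
    """Return the location's region label under one aggregation scheme."""
    if scheme not in location.region_memberships:
        raise KeyError(
            f"unknown aggregation scheme '{scheme}'; available: "
            f"{sorted(location.region_memberships)}"
        )
    return location.region_memberships[scheme]
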