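"""River-network chainage: projecting planar telemetry fixes onto the river.

The river is a tree: a mainstem polyline with chainage 0 km at the release
point, plus optional tributaries attached at known junction chainages.
Coordinates are planar metres (UTM-like, pre-projected); chainage is the
cumulative along-channel distance in kilometres, upstream-positive from the
release point.  A fix on a tributary carries the chainage *via its
junction*, so chainage is always "along-river distance from release".

Point-to-line projection is delegated to shapely; the tree-metric path
distance between projected fixes is computed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

__all__ = ["RiverNetwork", "ProjectedFix", "snap_to_river", "snap_track", "path_distance"]

MAINSTEM_ID = 0


@dataclass
class _Part:
    part_id: int
    coords: np.ndarray  # (N, 2) planar metres
    start_chainage_km: float  # chainage of the part's first vertex from release
    name: str = ""
    line: LineString = field(init=False, repr=False)
    length_km: float = field(init=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2 or len(self.coords) < 2:
            raise ValueError("a part needs at least two planar (x, y) vertices")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("part coordinates must be finite")
        seg = np.diff(self.coords, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seg_len <= 0):
            raise ValueError("non-increasing chainage: zero-length segment in part")
        self.line = LineString(self.coords)
        self.length_km = float(seg_len.sum() / 1000.0)

    @property
    def vertex_chainage_km(self) -> np.ndarray:
        seg = np.diff(self.coords, axis=0)
        s = np.concatenate(([0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))))
        return self.start_chainage_km + s / 1000.0


class RiverNetwork:
    """Tree-shaped river network indexed by chainage.

    Parameters
    ----------
    mainstem : (N, 2) array
        Mainstem vertices in planar metres; the first vertex is the release
        point (chainage 0).
    tributaries : list of (junction_chainage_km, coords), optional
        Each tributary's first vertex is its mouth on the mainstem; its
        chainage continues from the junction chainage.
    sections : dict, optional
        Named chainage intervals, e.g. ``{"narrow": (21, 54)}``.
    """

    def __init__(self, mainstem, tributaries=(), sections: dict | None = None):
        self.parts: list[_Part] = [
            _Part(MAINSTEM_ID, np.asarray(mainstem, float), 0.0, name="mainstem")
        ]
        self.junctions: list[tuple[int, float]] = []
        main_len = self.parts[0].length_km
        for i, (junction_km, coords) in enumerate(tributaries, start=1):
            if not (0.0 <= junction_km <= main_len):
                raise ValueError(
                    f"junction chainage {junction_km} outside mainstem [0, {main_len}]"
                )
            self.parts.append(
                _Part(i, np.asarray(coords, float), float(junction_km), name=f"trib{i}")
            )
            self.junctions.append((i, float(junction_km)))
        self.sections = dict(sections or {})

    @property
    def mainstem(self) -> _Part:
        return self.parts[0]

    @property
    def length_km(self) -> float:
        return self.mainstem.length_km

    def junction_of(self, part_id: int) -> float:
        for pid, j in self.junctions:
            if pid == part_id:
                return j
        raise KeyError(f"part {part_id} has no junction")

    def point_at_chainage(self, chainage_km: float) -> np.ndarray:
        """Planar mainstem point at a given chainage (for synthesis)."""
        pt = self.mainstem.line.interpolate(chainage_km * 1000.0)
        return np.array([pt.x, pt.y])

    # -- GeoJSON round trip --------------------------------------------------

    def to_geojson(self, path=None) -> dict:
        features = []
        for part in self.parts:
            props = {
                "part_id": part.part_id,
                "name": part.name,
                "chainage_km": part.start_chainage_km,
            }
            features.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": {
                        "type": "LineString",
                        "coordinates": part.coords.tolist(),
                    },
                }
            )
        obj = {
            "type": "FeatureCollection",
            "features": features,
            "properties": {"sections": {k: list(v) for k, v in self.sections.items()}},
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh)
        return obj

    @classmethod
    def from_geojson(cls, source) -> "RiverNetwork":
        import os

        if hasattr(source, "read"):
            obj = json.load(source)
        elif isinstance(source, (str, bytes, os.PathLike)):
            with open(source) as fh:
                obj = json.load(fh)
        else:
            obj = source
        feats = sorted(obj["features"], key=lambda f: f["properties"]["part_id"])
        mainstem = np.asarray(feats[0]["geometry"]["coordinates"], float)
        tribs = [
            (f["properties"]["chainage_km"],
             np.asarray(f["geometry"]["coordinates"], float))
            for f in feats[1:]
        ]
        sections = {
            k: tuple(v)
            for k, v in obj.get("properties", {}).get("sections", {}).items()
        }
        return cls(mainstem, tribs, sections=sections)


@dataclass(frozen=True)
class ProjectedFix:
    """A telemetry fix snapped onto the river network."""

    fish_id: str | None
    timestamp: object
    part_id: int
    chainage_km: float  # along-river distance upstream of release (via junction)
    offset_m: float  # perpendicular snap distance
    ambiguous: bool = False  # runner-up part within 50 m of the best offset

    def __post_init__(self):
        if self.offset_m < 0:
            raise ValueError("offset must be non-negative")


def snap_to_river(
    point, network: RiverNetwork, fish_id=None, timestamp=None,
    ambiguity_margin_m: float = 50.0,
) -> ProjectedFix:
    """Project a planar point onto the nearest river segment.

    Returns the orthogonal projection over all parts, with chainage
    interpolated linearly within the segment.  Ties are broken by lower
    part id, then lower chainage.  The fix is flagged ambiguous when a
    different part lies within ``ambiguity_margin_m`` of the best offset —
    relevant near tributary mouths.
    """
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("fix coordinates must be finite")
    p = Point(x, y)

    candidates = []  # (offset_m, part_id, chainage_km)
    for part in network.parts:
        offset = part.line.distance(p)
        s_km = part.line.project(p) / 1000.0
        candidates.append((float(offset), part.part_id, part.start_chainage_km + s_km))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    best = candidates[0]
    ambiguous = any(
        c[1] != best[1] and c[0] - best[0] < ambiguity_margin_m for c in candidates[1:]
    )
    return ProjectedFix(
        fish_id=fish_id,
        timestamp=timestamp,
        part_id=best[1],
        chainage_km=best[2],
        offset_m=best[0],
        ambiguous=ambiguous,
    )


def snap_track(track: pd.DataFrame, network: RiverNetwork) -> pd.DataFrame:
    """Snap a table of fixes (columns fish_id, timestamp, x_m, y_m).

    Returns the table with part_id, chainage_km, offset_m and ambiguity
    columns appended.
    """
    fixes = [
        snap_to_river(
            (row.x_m, row.y_m), network,
            fish_id=row.fish_id, timestamp=row.timestamp,
        )
        for row in track.itertuples()
    ]
    out = track.copy()
    out["part_id"] = [f.part_id for f in fixes]
    out["chainage_km"] = [f.chainage_km for f in fixes]
    out["offset_m"] = [f.offset_m for f in fixes]
    out["ambiguous"] = [f.ambiguous for f in fixes]
    return out


def path_distance(fix_a: ProjectedFix, fix_b: ProjectedFix, network: RiverNetwork) -> float:
    """Along-river (tree-metric) distance in km between two projected fixes.

    On the same part this is the absolute chainage difference; across a
    junction the path runs down the tributary to its mouth and along the
    mainstem.  Symmetric by construction.
    """
    known = {p.part_id for p in network.parts}
    for f in (fix_a, fix_b):
        if f.part_id not in known:
            raise ValueError(f"fix references unknown part {f.part_id}")

    if fix_a.part_id == fix_b.part_id:
        return abs(fix_a.chainage_km - fix_b.chainage_km)

    def to_mainstem(fix: ProjectedFix) -> tuple[float, float]:
        """(distance to mainstem junction, junction chainage)."""
        if fix.part_id == MAINSTEM_ID:
            return 0.0, fix.chainage_km
        j = network.junction_of(fix.part_id)
        return fix.chainage_km - j, j

    da, ja = to_mainstem(fix_a)
    db, jb = to_mainstem(fix_b)
    return da + db + abs(ja - jb)
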