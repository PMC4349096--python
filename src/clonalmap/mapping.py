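"""Marker grouping, TSP ordering, and linkage-map construction.

Markers are grouped by single-linkage transitive closure over pairs whose
combined recombination-frequency estimate falls below a threshold (default
0.3).  Each group is ordered by solving an open-path Traveling Salesman
Problem on the pairwise estimates: nearest-neighbour construction from
every start, improved by Two-opt segment reversals until 2-optimal.  The
objective is the sum of adjacent estimates, which is monotone in map length
for linked neighbours but stays finite where Haldane distance would not.

Three maps are built per group: the combined map from the combined
estimates, and the female/male maps from the parental estimates between
retained neighbours (female maps drop category-II markers, male maps drop
category-III markers, since those segregate in only one parent).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .estimation import RecombMatrix
from .markers import MarkerCategory

#: TSP objective contribution of an adjacency whose r is inestimable:
#: treated as unlinked without being forbidden.
MASKED_PENALTY = 0.5


class MapFunction(enum.Enum):
    HALDANE = "haldane"
    KOSAMBI = "kosambi"

    @classmethod
    def parse(cls, label: "str | MapFunction") -> "MapFunction":
        if isinstance(label, cls):
            return label
        try:
            return cls(str(label).lower())
        except ValueError:
            raise ValueError(f"unknown mapping function {label!r}") from None


class UndefinedDistanceError(ValueError):
    """Raised when converting r >= 0.5 (unlinked) to a map distance."""


def map_distance(r: float, fn: MapFunction | str = MapFunction.HALDANE) -> float:
    """Convert a recombination frequency to a map distance in centiMorgans.

    Haldane (no interference):  d = -50 ln(1 - 2r)
    Kosambi:                    d = 25 ln((1 + 2r)/(1 - 2r))
    """
    fn = MapFunction.parse(fn)
    if not 0.0 <= r < 0.5:
        raise UndefinedDistanceError(f"map distance undefined for r = {r!r}")
    if fn is MapFunction.HALDANE:
        return -50.0 * math.log1p(-2.0 * r)
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def inverse_map_distance(d: float, fn: MapFunction | str = MapFunction.HALDANE) -> float:
    """Map distance (cM) back to recombination frequency."""
    fn = MapFunction.parse(fn)
    if d < 0:
        raise ValueError("negative distance")
    if fn is MapFunction.HALDANE:
        return 0.5 * (1.0 - math.exp(-d / 50.0))
    return 0.5 * math.tanh(d / 50.0)


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroup:
    members: list[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GroupingResult:
    groups: list[LinkageGroup]
    singletons: list[str]


def group_markers(rm: RecombMatrix, threshold: float = 0.3) -> GroupingResult:
    """Single-linkage grouping: markers joined when estimable r < threshold.

    Markers linked to nothing are reported as singletons (they would be
    dropped from mapping).  Groups preserve the input marker order and are
    sorted by their first member.
    """
    ids = rm.marker_ids
    parent = {m: m for m in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if bool(rm.mask.loc[a, b]) and float(rm.r.loc[a, b]) < threshold:
                parent[find(a)] = find(b)

    clusters: dict[str, list[str]] = {}
    for m in ids:
        clusters.setdefault(find(m), []).append(m)
    groups = [LinkageGroup(v) for v in clusters.values() if len(v) > 1]
    groups.sort(key=lambda g: ids.index(g.members[0]))
    singletons = [v[0] for v in clusters.values() if len(v) == 1]
    return GroupingResult(groups=groups, singletons=singletons)


# ---------------------------------------------------------------------------
# Ordering (open-path TSP: nearest neighbour + Two-opt)
# ---------------------------------------------------------------------------

def _distance_matrix(members: list[str], rm: RecombMatrix) -> np.ndarray:
    sub_r = rm.r.loc[members, members].to_numpy(dtype=float)
    sub_mask = rm.mask.loc[members, members].to_numpy(dtype=bool)
    d = np.where(sub_mask, sub_r, MASKED_PENALTY)
    np.fill_diagonal(d, 0.0)
    return d


def _path_cost(path: list[int], d: np.ndarray) -> float:
    return float(sum(d[path[k], path[k + 1]] for k in range(len(path) - 1)))


def _nearest_neighbour(d: np.ndarray, start: int) -> list[int]:
    m = d.shape[0]
    unvisited = set(range(m))
    unvisited.remove(start)
    path = [start]
    while unvisited:
        last = path[-1]
        # ties broken by index for reproducibility
        nxt = min(unvisited, key=lambda j: (d[last, j], j))
        unvisited.remove(nxt)
        path.append(nxt)
    return path


def _two_opt(path: list[int], d: np.ndarray) -> list[int]:
    """Reverse internal segments while any reversal shortens the open path."""
    m = len(path)
    improved = True
    while improved:
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                # reversing path[i..j] changes edges (i-1,i) and (j,j+1)
                before = 0.0
                after = 0.0
                if i > 0:
                    before += d[path[i - 1], path[i]]
                    after += d[path[i - 1], path[j]]
                if j < m - 1:
                    before += d[path[j], path[j + 1]]
                    after += d[path[i], path[j + 1]]
                if after < before - 1e-12:
                    path[i:j + 1] = reversed(path[i:j + 1])
                    improved = True
    return path


def order_markers(group: LinkageGroup | list[str], rm: RecombMatrix) -> list[str]:
    """Order one linkage group by nearest-neighbour + Two-opt.

    Nearest-neighbour paths are built from every possible start, the
    cheapest is polished by Two-opt, and the result is canonicalized so
    the endpoint earlier in the input marker list comes first.
    """
    members = group.members if isinstance(group, LinkageGroup) else list(group)
    if len(members) == 1:
        return list(members)
    d = _distance_matrix(members, rm)
    best_path: list[int] | None = None
    best_cost = math.inf
    for start in range(len(members)):
        path = _two_opt(_nearest_neighbour(d, start), d)
        cost = _path_cost(path, d)
        if cost < best_cost - 1e-12:
            best_cost, best_path = cost, path
    assert best_path is not None
    if best_path[-1] < best_path[0]:
        best_path = best_path[::-1]
    return [members[k] for k in best_path]


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------

class MapKind(enum.Enum):
    COMBINED = "combined"
    FEMALE = "female"
    MALE = "male"


@dataclass
class LinkageMap:
    """An ordered linkage map with cumulative positions in cM.

    ``interval_r`` holds the adjacent recombination estimates used;
    ``interval_flagged`` marks intervals whose own estimate was missing or
    at the 0.5 boundary and was borrowed from the nearest estimable
    flanking interval.
    """

    kind: MapKind
    mapfn: MapFunction
    markers: list[str]
    interval_r: list[float] = field(default_factory=list)
    interval_flagged: list[bool] = field(default_factory=list)

    @property
    def distances(self) -> list[float]:
        return [map_distance(r, self.mapfn) for r in self.interval_r]

    @property
    def positions(self) -> list[float]:
        pos = [0.0]
        for d in self.distances:
            pos.append(pos[-1] + d)
        return pos

    @property
    def length(self) -> float:
        return self.positions[-1] if self.markers else 0.0


def _fill_intervals(raw: list[float | None]) -> tuple[list[float], list[bool]]:
    """Replace missing interval estimates by the nearest estimable flanking one."""
    known = [k for k, v in enumerate(raw) if v is not None]
    filled: list[float] = []
    flagged: list[bool] = []
    for k, v in enumerate(raw):
        if v is not None:
            filled.append(v)
            flagged.append(False)
        elif known:
            nearest = min(known, key=lambda j: (abs(j - k), j))
            filled.append(raw[nearest])  # type: ignore[arg-type]
            flagged.append(True)
        else:  # no estimable interval anywhere: degenerate zero-length map
            filled.append(0.0)
            flagged.append(True)
    return filled, flagged


def _adjacent_r(rm: RecombMatrix, a: str, b: str, which: str) -> float | None:
    if not bool(rm.mask.loc[a, b]):
        return None
    if which == "r":
        val = float(rm.r.loc[a, b])
    else:
        val = float(rm.r_f.loc[a, b] if which == "rf" else rm.r_m.loc[a, b])
        if math.isnan(val):
            return None
        if val > 0.5:  # repulsion-phase raw value encodes phase, not distance
            val = 1.0 - val
    if not val < 0.5 - 1e-12:
        return None
    return val


def build_maps(
    order: list[str],
    rm: RecombMatrix,
    mapfn: MapFunction | str = MapFunction.HALDANE,
) -> dict[MapKind, LinkageMap]:
    """Build the combined, female, and male maps for one ordered group.

    The female and male maps keep the combined order restricted to markers
    polymorphic in that parent, with interval distances re-estimated
    directly between the retained neighbours (not summed over removed
    markers).
    """
    mapfn = MapFunction.parse(mapfn)
    retained = {
        MapKind.COMBINED: list(order),
        MapKind.FEMALE: [m for m in order if rm.category(m) is not MarkerCategory.II],
        MapKind.MALE: [m for m in order if rm.category(m) is not MarkerCategory.III],
    }
    which = {MapKind.COMBINED: "r", MapKind.FEMALE: "rf", MapKind.MALE: "rm"}
    maps: dict[MapKind, LinkageMap] = {}
    for kind, markers in retained.items():
        raw = [
            _adjacent_r(rm, markers[k], markers[k + 1], which[kind])
            for k in range(len(markers) - 1)
        ]
        interval_r, flagged = _fill_intervals(raw)
        maps[kind] = LinkageMap(
            kind=kind,
            mapfn=mapfn,
            markers=markers,
            interval_r=interval_r,
            interval_flagged=flagged,
        )
    return maps
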