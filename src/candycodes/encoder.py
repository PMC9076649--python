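"""Convert a CandyCode particle pattern into its canonical string set.

The pipeline mirrors how a human would describe each particle's local
neighborhood:

1. Compute the Delaunay triangulation of the particle centers; its edges
   define which particles are neighbors.
2. For each particle (the *center*), read its neighbors' color letters
   moving clockwise around the center.  In the y-down image frame,
   clockwise as displayed corresponds to increasing ``atan2`` angle.
3. Make the cyclic reading order canonical by rotating it to its
   lexicographically smallest start (this generalizes "start at the
   alphabetically first neighbor, break ties by the letters that follow"),
   then prepend the center's letter.
4. Discard low-quality strings: centers on the convex hull (edge particles
   have incomplete neighborhoods), strings with fewer than four distinct
   colors (uninformative, especially with an excess of white particles),
   and centers with too few neighbors.

The surviving multiset of strings is the code's database representation.
It is invariant to translation and rotation of the photograph, and two
photographs of the same pill typically agree on about half their strings —
far more than two different pills ever share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError

from ._kernels import STRING_WIDTH, encode_from_triangulation
from .core import CandyCode, CandyCodeError, Particle, StringSet

__all__ = [
    "EncoderConfig",
    "NeighborGraph",
    "EncodingError",
    "build_neighbor_graph",
    "order_neighbors_clockwise",
    "canonical_rotation",
    "encode_neighborhood",
    "encode_candycode",
]


class EncodingError(CandyCodeError):
    """The particle pattern cannot be encoded (degenerate geometry etc.)."""


@dataclass(frozen=True)
class EncoderConfig:
    """Discard-filter settings for string encoding.

    discard_hull
        Drop strings whose center particle lies on the convex hull; edge
        particles have truncated neighborhoods whose short strings repeat
        across codes.
    min_distinct_colors
        Minimum number of distinct letters (center included) a retained
        string must contain.  The default of 4 suppresses low-diversity
        strings such as near-all-white neighborhoods.
    min_neighbors
        Minimum neighbor count for a retained string.
    """

    discard_hull: bool = True
    min_distinct_colors: int = 4
    min_neighbors: int = 2

    def __post_init__(self) -> None:
        if self.min_distinct_colors < 1:
            raise ValueError("min_distinct_colors must be >= 1")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")


DEFAULT_CONFIG = EncoderConfig()


@dataclass(frozen=True)
class NeighborGraph:
    """Delaunay adjacency of a particle pattern plus convex-hull membership."""

    vertex_count: int
    adjacency: tuple[frozenset, ...]
    hull_vertices: frozenset

    def degree(self, i: int) -> int:
        return len(self.adjacency[i])


def _triangulate(points: np.ndarray) -> Delaunay:
    if len(points) < 3:
        raise EncodingError("degenerate geometry: need at least 3 particles")
    try:
        tri = Delaunay(points)
    except (QhullError, ValueError) as exc:
        raise EncodingError(f"degenerate geometry: {exc}") from exc
    if tri.simplices.shape[0] == 0:
        raise EncodingError("degenerate geometry: collinear points")
    return tri


def build_neighbor_graph(code: CandyCode) -> NeighborGraph:
    """Delaunay neighbor graph of a code's particles.

    Raises EncodingError for fewer than 3 particles or collinear points.
    Cocircular point sets admit more than one valid triangulation; the one
    returned is implementation-defined but always a valid Delaunay
    triangulation.
    """
    points = code.coordinates()
    tri = _triangulate(points)
    n = len(points)
    adj: list[set] = [set() for _ in range(n)]
    for a, b, c in tri.simplices:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    hull = frozenset(int(v) for v in np.unique(tri.convex_hull))
    return NeighborGraph(n, tuple(frozenset(s) for s in adj), hull)


def order_neighbors_clockwise(
    center: Particle, neighbors: Sequence[Particle]
) -> list[int]:
    """Indices of ``neighbors`` sorted clockwise around ``center``.

    Clockwise as displayed on screen: in the y-down image frame this is
    increasing ``atan2(y - y_c, x - x_c)``.  The result is a cyclic order;
    the starting element carries no meaning.
    """
    if not neighbors:
        raise EncodingError("at least one neighbor required")
    angles = []
    for i, p in enumerate(neighbors):
        dx, dy = p.x - center.x, p.y - center.y
        if dx == 0 and dy == 0:
            raise EncodingError(f"neighbor {i} coincides with center")
        angles.append((math.atan2(dy, dx), i))
    return [i for _, i in sorted(angles)]


def canonical_rotation(cycle: Sequence[str]) -> str:
    """Lexicographically smallest rotation of a cyclic letter sequence.

    Reading direction is preserved (the cycle is given clockwise); only the
    starting point changes.  Starting at the alphabetically first letter
    and breaking ties by the letters that follow clockwise is exactly the
    minimal rotation, so this rule resolves arbitrarily deep ties.
    """
    if not cycle:
        raise ValueError("empty cycle")
    s = "".join(cycle)
    doubled = s + s
    g = len(s)
    return min(doubled[i : i + g] for i in range(g))


def encode_neighborhood(center_color: str, ordered_cycle: Sequence[str]) -> str:
    """Center letter followed by the canonical rotation of its neighbor cycle."""
    return center_color + canonical_rotation(ordered_cycle)


def _ascii_colors(code: CandyCode) -> np.ndarray:
    return np.frombuffer("".join(code.colors()).encode("ascii"), dtype=np.uint8)


def encode_candycode(
    code: CandyCode, config: EncoderConfig = DEFAULT_CONFIG
) -> StringSet:
    """Encode a CandyCode into its retained multiset of neighborhood strings.

    Produces one candidate string per particle (before filtering there are
    exactly as many candidate strings as particles), then applies the
    discard filters in ``config``.
    """
    points = code.coordinates()
    tri = _triangulate(points)
    colors = _ascii_colors(code)
    raw, count = _encode_simplices(tri, points, colors, config)
    strings = [
        raw[i].tobytes().rstrip(b"\x00").decode("ascii") for i in range(count)
    ]
    return StringSet.from_iterable(code.id, strings)


def _encode_simplices(
    tri: Delaunay, points: np.ndarray, colors: np.ndarray, config: EncoderConfig
):
    """Shared kernel driver returning (uint8 rows, count)."""
    n = len(points)
    hull_mask = np.zeros(n, dtype=np.bool_)
    hull_mask[np.unique(tri.convex_hull)] = True
    raw, count = encode_from_triangulation(
        np.ascontiguousarray(tri.simplices, dtype=np.int64),
        points,
        hull_mask,
        colors,
        config.discard_hull,
        config.min_distinct_colors,
        config.min_neighbors,
    )
    if count < 0:
        raise EncodingError(
            f"neighborhood exceeds {STRING_WIDTH - 2} neighbors; "
            "pattern too degenerate to encode"
        )
    return raw, count


def encode_points_raw(
    points: np.ndarray, colors: np.ndarray, config: EncoderConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Encode a raw point pattern to zero-padded uint8 ASCII string rows.

    Bulk interface used by the library simulator: identical strings to
    ``encode_candycode`` but without constructing Python objects.
    ``colors`` is a uint8 array of ASCII letter codes.
    """
    points = np.ascontiguousarray(points, dtype=np.float64)
    tri = _triangulate(points)
    raw, count = _encode_simplices(tri, points, colors, config)
    return raw[:count]
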