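"""Compiled kernels for particle packing and neighborhood-string encoding.

These numba routines are the hot path behind the simulator and encoder:
Monte-Carlo library sweeps encode hundreds of thousands of codes, so the
per-code work (random sequential adsorption, adjacency extraction, clockwise
ordering, canonical rotation, discard filters) runs in compiled code on
numeric arrays.  Strings are produced as rows of a zero-padded uint8 matrix
of ASCII letters; callers decode them only when Python strings are needed.

The public modules (`simulator`, `encoder`) wrap these kernels and own all
validation and error reporting.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Width of an encoded-string row: 1 center letter + up to STRING_WIDTH-2
#: neighbor letters + 1 reserved trailing byte (used by the library matcher
#: to disambiguate within-code duplicate strings).  Delaunay degrees of
#: random planar points essentially never approach this bound.
STRING_WIDTH = 24


@njit(cache=True)
def rsa_pack(n, pill_radius, particle_radius, max_attempts, seed):
    """Random sequential adsorption of n disks on a circular pill face.

    Proposes centers uniformly on the disk of radius pill_radius -
    particle_radius (rejection from the bounding square) and rejects any
    proposal closer than 2 * particle_radius to an accepted center.

    Returns (points, n_placed); n_placed < n signals packing failure after
    max_attempts proposals for some particle.
    """
    np.random.seed(seed)
    pts = np.empty((n, 2), dtype=np.float64)
    lim = pill_radius - particle_radius
    lim2 = lim * lim
    d2 = (2.0 * particle_radius) ** 2
    for k in range(n):
        placed = False
        for _ in range(max_attempts):
            x = np.random.uniform(-lim, lim)
            y = np.random.uniform(-lim, lim)
            if x * x + y * y > lim2:
                continue
            ok = True
            for j in range(k):
                dx = pts[j, 0] - x
                dy = pts[j, 1] - y
                if dx * dx + dy * dy < d2:
                    ok = False
                    break
            if ok:
                pts[k, 0] = x
                pts[k, 1] = y
                placed = True
                break
        if not placed:
            return pts, k
    return pts, n


@njit(cache=True)
def sample_colors(n, cum_probs, seed):
    """Draw n color indices from the cumulative distribution cum_probs."""
    np.random.seed(seed)
    out = np.empty(n, dtype=np.uint8)
    m = cum_probs.shape[0]
    for i in range(n):
        u = np.random.random()
        j = 0
        while j < m - 1 and u >= cum_probs[j]:
            j += 1
        out[i] = j
    return out


@njit(cache=True)
def _canonical_start(seq):
    """Index of the lexicographically minimal rotation of uint8 cycle seq."""
    g = seq.shape[0]
    best = 0
    for s in range(1, g):
        # compare rotation s with rotation best
        for t in range(g):
            a = seq[(s + t) % g]
            b = seq[(best + t) % g]
            if a < b:
                best = s
                break
            if a > b:
                break
    return best


@njit(cache=True)
def encode_from_triangulation(
    simplices, pts, hull_mask, colors, discard_hull, min_distinct_colors, min_neighbors
):
    """Convert a Delaunay triangulation into retained neighborhood strings.

    For every vertex (the center), its Delaunay neighbors are ordered by
    increasing atan2 angle in the y-down image frame (clockwise as
    displayed), the cycle is rotated to its lexicographically smallest
    start, and the center letter is prepended.  Strings are discarded when
    the center lies on the convex hull (if discard_hull), when the string
    has fewer than min_distinct_colors distinct letters (center included),
    or when the center has fewer than min_neighbors neighbors.

    Returns (out, count): out[:count] are zero-padded uint8 ASCII rows.
    """
    n = pts.shape[0]
    m = simplices.shape[0]

    # Directed edge keys center*n + neighbor; sorting groups by center and
    # deduplicates edges shared between adjacent triangles.
    keys = np.empty(6 * m, dtype=np.int64)
    for t in range(m):
        a = simplices[t, 0]
        b = simplices[t, 1]
        c = simplices[t, 2]
        keys[6 * t] = a * n + b
        keys[6 * t + 1] = b * n + c
        keys[6 * t + 2] = c * n + a
        keys[6 * t + 3] = b * n + a
        keys[6 * t + 4] = c * n + b
        keys[6 * t + 5] = a * n + c
    keys.sort()
    n_edges = 0
    for i in range(keys.shape[0]):
        if i == 0 or keys[i] != keys[i - 1]:
            n_edges += 1
    centers = np.empty(n_edges, dtype=np.int64)
    neighbors = np.empty(n_edges, dtype=np.int64)
    e = 0
    for i in range(keys.shape[0]):
        if i == 0 or keys[i] != keys[i - 1]:
            centers[e] = keys[i] // n
            neighbors[e] = keys[i] % n
            e += 1

    # Sort each center's neighbors by angle.  Composite float key works
    # because the angle term (atan2 + 4) lies strictly inside (0, 8).
    sortkey = np.empty(n_edges, dtype=np.float64)
    for i in range(n_edges):
        ci = centers[i]
        ni = neighbors[i]
        ang = np.arctan2(pts[ni, 1] - pts[ci, 1], pts[ni, 0] - pts[ci, 0])
        sortkey[i] = ci * 8.0 + (ang + 4.0)
    order = np.argsort(sortkey)

    out = np.zeros((n, STRING_WIDTH), dtype=np.uint8)
    count = 0
    seq = np.empty(STRING_WIDTH, dtype=np.uint8)
    i = 0
    while i < n_edges:
        ci = centers[order[i]]
        j = i
        while j < n_edges and centers[order[j]] == ci:
            j += 1
        g = j - i
        if (not discard_hull or not hull_mask[ci]) and g >= min_neighbors:
            if g + 1 > STRING_WIDTH - 1:
                # would overflow the fixed row width; signal to the caller
                return out, -1
            for t in range(g):
                seq[t] = colors[neighbors[order[i + t]]]
            # distinct letters, center included
            mask = np.int64(1) << np.int64(colors[ci] - 65)
            distinct = 1
            for t in range(g):
                bit = np.int64(1) << np.int64(seq[t] - 65)
                if mask & bit == 0:
                    distinct += 1
                    mask |= bit
            if distinct >= min_distinct_colors:
                start = _canonical_start(seq[:g])
                out[count, 0] = colors[ci]
                for t in range(g):
                    out[count, 1 + t] = seq[(start + t) % g]
                count += 1
        i = j
    return out, count
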