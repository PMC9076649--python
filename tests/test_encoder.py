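import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from candycodes import (
    ALPHABETS,
    CandyCode,
    EncoderConfig,
    EncodingError,
    Particle,
    SimConfig,
    build_neighbor_graph,
    canonical_rotation,
    encode_candycode,
    encode_neighborhood,
    order_neighbors_clockwise,
    simulate_candycode,
)

A = ALPHABETS["A"]


def make_code(points, colors, alphabet=A):
    return CandyCode(
        "t", [Particle(float(x), float(y), c) for (x, y), c in zip(points, colors)], alphabet
    )


def brute_force_delaunay_edges(points):
    """All edges of triangles whose circumcircle is empty of other points.

    O(n^4) oracle: independent of scipy's triangulation.  Assumes general
    position (no 4 cocircular points).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                ax, ay = pts[i]
                bx, by = pts[j]
                cx, cy = pts[k]
                d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(d) < 1e-14:
                    continue  # collinear triple
                ux = (
                    (ax**2 + ay**2) * (by - cy)
                    + (bx**2 + by**2) * (cy - ay)
                    + (cx**2 + cy**2) * (ay - by)
                ) / d
                uy = (
                    (ax**2 + ay**2) * (cx - bx)
                    + (bx**2 + by**2) * (ax - cx)
                    + (cx**2 + cy**2) * (bx - ax)
                ) / d
                r2 = (ax - ux) ** 2 + (ay - uy) ** 2
                d2 = (pts[:, 0] - ux) ** 2 + (pts[:, 1] - uy) ** 2
                mask = np.ones(n, bool)
                mask[[i, j, k]] = False
                if np.all(d2[mask] > r2 * (1 + 1e-12)):
                    edges.update({(i, j), (j, k), (i, k)})
    return edges


def reference_encode(code, config=EncoderConfig()):
    """Compose the public single-neighborhood operations into a string set.

    Independent route against which the bulk encoder is checked.
    """
    graph = build_neighbor_graph(code)
    out = []
    for i, p in enumerate(code.particles):
        if config.discard_hull and i in graph.hull_vertices:
            continue
        nbr_idx = sorted(graph.adjacency[i])
        if len(nbr_idx) < config.min_neighbors:
            continue
        nbrs = [code.particles[j] for j in nbr_idx]
        order = order_neighbors_clockwise(p, nbrs)
        cycle = [nbrs[j].color for j in order]
        s = encode_neighborhood(p.color, cycle)
        if len(set(s)) < config.min_distinct_colors:
            continue
        out.append(s)
    return sorted(out)


class TestNeighborGraph:
    def test_single_triangle(self):
        code = make_code([(0, 0), (1, 0), (0, 1)], "WGD")
        g = build_neighbor_graph(code)
        assert g.vertex_count == 3
        assert all(len(a) == 2 for a in g.adjacency)
        assert g.hull_vertices == frozenset({0, 1, 2})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_empty_circumcircle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, size=(20, 2))
        code = make_code(pts, ["W"] * 20)
        g = build_neighbor_graph(code)
        got = {
            (min(i, j), max(i, j))
            for i in range(20)
            for j in g.adjacency[i]
        }
        assert got == brute_force_delaunay_edges(pts)

    def test_adjacency_symmetric_no_self_loops(self, sim_code):
        g = build_neighbor_graph(sim_code)
        for i, nbrs in enumerate(g.adjacency):
            assert i not in nbrs
            for j in nbrs:
                assert i in g.adjacency[j]

    def test_cocircular_square(self):
        code = make_code([(0, 0), (1, 0), (1, 1), (0, 1)], "WGDR")
        g = build_neighbor_graph(code)
        sides = {(0, 1), (1, 2), (2, 3), (0, 3)}
        edges = {
            (min(i, j), max(i, j)) for i in range(4) for j in g.adjacency[i]
        }
        assert sides <= edges
        diagonals = edges - sides
        assert diagonals in ({(0, 2)}, {(1, 3)})  # exactly one diagonal

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(EncodingError, match="degenerate"):
            build_neighbor_graph(make_code([(0, 0), (1, 1)], "WG"))
        with pytest.raises(EncodingError, match="degenerate"):
            build_neighbor_graph(
                make_code([(0, 0), (1, 1), (2, 2), (3, 3)], "WGDR")
            )


class TestClockwiseOrdering:
    def test_cross_layout_reads_clockwise_on_screen(self):
        # y grows downward: above, right, below, left as displayed
        center = Particle(0, 0, "W")
        nbrs = [
            Particle(0, -1, "D"),  # above
            Particle(1, 0, "G"),  # right
            Particle(0, 1, "R"),  # below
            Particle(-1, 0, "Y"),  # left
        ]
        assert order_neighbors_clockwise(center, nbrs) == [0, 1, 2, 3]

    def test_single_neighbor(self):
        assert order_neighbors_clockwise(Particle(0, 0, "W"), [Particle(1, 1, "G")]) == [0]

    def test_coincident_neighbor_rejected(self):
        with pytest.raises(EncodingError):
            order_neighbors_clockwise(Particle(0, 0, "W"), [Particle(0, 0, "G")])

    def test_rotation_invariance_of_cyclic_order(self, rng):
        center = Particle(0.0, 0.0, "W")
        angles = np.sort(rng.uniform(-math.pi, math.pi, 7))
        nbrs = [Particle(math.cos(a), math.sin(a), "G") for a in angles]
        theta = 1.1
        rot = [
            Particle(
                p.x * math.cos(theta) - p.y * math.sin(theta),
                p.x * math.sin(theta) + p.y * math.cos(theta),
                p.color,
            )
            for p in nbrs
        ]
        o1 = order_neighbors_clockwise(center, nbrs)
        o2 = order_neighbors_clockwise(center, rot)
        # same cyclic sequence, possibly different start
        k = o2.index(o1[0])
        assert o2[k:] + o2[:k] == o1


class TestCanonicalRotation:
    @pytest.mark.parametrize(
        "cycle,expected",
        [
            # worked neighborhood examples: cycles as read clockwise
            ("DGRPWW", "DGRPWW"),
            ("GWWGY", "GWWGY"),  # GW... beats GY... via the following letter
            ("WWW", "WWW"),
            ("YG", "GY"),
        ],
    )
    def test_examples(self, cycle, expected):
        assert canonical_rotation(cycle) == expected

    @given(
        st.lists(st.sampled_from("DGLOPRWY"), min_size=1, max_size=10),
        st.integers(0, 9),
    )
    @settings(deadline=None, derandomize=True)
    def test_start_independence(self, cycle, shift):
        shift = shift % len(cycle)
        rotated = cycle[shift:] + cycle[:shift]
        assert canonical_rotation(cycle) == canonical_rotation(rotated)

    def test_result_is_a_rotation_of_input(self):
        s = "WGDWY"
        out = canonical_rotation(s)
        assert out in (s + s)
        assert len(out) == len(s)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            canonical_rotation("")


class TestEncodeNeighborhood:
    def test_pink_center_worked_example(self):
        assert encode_neighborhood("P", "DGRPWW") == "PDGRPWW"

    def test_white_center_tie_break_example(self):
        # two G candidates; the one followed by W (alphabetically before Y) wins
        assert encode_neighborhood("W", ["G", "W", "W", "G", "Y"]) == "WGWWGY"

    def test_single_neighbor(self):
        assert encode_neighborhood("G", ["Y"]) == "GY"


class TestEncodeCandyCode:
    def test_candidate_count_equals_particle_count_without_filters(self):
        code = simulate_candycode(SimConfig(seed=7))
        cfg = EncoderConfig(discard_hull=False, min_distinct_colors=1, min_neighbors=1)
        assert encode_candycode(code, cfg).total() == len(code)

    def test_monochrome_code_encodes_to_empty_set(self, rng):
        pts = rng.uniform(0, 1, size=(30, 2))
        code = make_code(pts, ["W"] * 30)
        assert encode_candycode(code).total() == 0

    def test_matches_reference_composition(self, sim_codes):
        for cfg in [
            EncoderConfig(),
            EncoderConfig(discard_hull=False),
            EncoderConfig(min_distinct_colors=1, min_neighbors=1, discard_hull=False),
        ]:
            for code in sim_codes:
                got = encode_candycode(code, cfg).as_sorted_list()
                assert got == reference_encode(code, cfg)

    def test_filter_soundness(self, sim_codes):
        cfg = EncoderConfig()
        for code in sim_codes:
            for s, mult in encode_candycode(code, cfg).strings.items():
                assert mult >= 1
                assert len(set(s)) >= cfg.min_distinct_colors
                assert len(s) - 1 >= cfg.min_neighbors
                assert set(s) <= set(code.alphabet.letters)

    def test_determinism(self, sim_code):
        assert encode_candycode(sim_code) == encode_candycode(sim_code)

    def test_rigid_motion_invariance(self, sim_code):
        base = encode_candycode(sim_code).strings
        theta = 0.7
        c, s = math.cos(theta), math.sin(theta)
        moved = CandyCode(
            sim_code.id,
            [
                Particle(p.x * c - p.y * s + 11.0, p.x * s + p.y * c - 3.5, p.color)
                for p in sim_code.particles
            ],
            sim_code.alphabet,
        )
        assert encode_candycode(moved).strings == base

    def test_mirror_reverses_neighbor_cycles(self, sim_code):
        """Reflection flips the reading direction of every neighborhood."""
        mirrored = CandyCode(
            sim_code.id,
            [Particle(-p.x, p.y, p.color) for p in sim_code.particles],
            sim_code.alphabet,
        )
        got = sorted(encode_candycode(mirrored).as_sorted_list())
        graph = build_neighbor_graph(sim_code)
        expected = []
        cfg = EncoderConfig()
        for i, p in enumerate(sim_code.particles):
            if i in graph.hull_vertices:
                continue
            nbr_idx = sorted(graph.adjacency[i])
            if len(nbr_idx) < cfg.min_neighbors:
                continue
            nbrs = [sim_code.particles[j] for j in nbr_idx]
            order = order_neighbors_clockwise(p, nbrs)
            cycle = [nbrs[j].color for j in order][::-1]  # reversed reading
            s = encode_neighborhood(p.color, cycle)
            if len(set(s)) >= cfg.min_distinct_colors:
                expected.append(s)
        assert got == sorted(expected)
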