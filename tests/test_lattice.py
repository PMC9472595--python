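"""Tubule geometry: rollup arithmetic, ideal embeddings, dihedral angles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helitube import (
    LatticeConstants,
    TubuleIndices,
    build_disk,
    circumference,
    classify_geometry,
    classify_geometry_full,
    diameter,
    ideal_dihedrals,
    ideal_embedding,
)
from helitube.lattice import InvalidGeometryError


class TestCircumference:
    @pytest.mark.parametrize(
        "mn, expected",
        [((10, 0), 10.0), ((1, 0), 1.0), ((9, 4), math.sqrt(133.0))],
    )
    def test_examples(self, mn, expected):
        assert circumference(TubuleIndices(*mn)) == pytest.approx(expected, abs=1e-12)

    def test_rollup_norm_oracle(self):
        # |m*a1 + n*a2| with 60-degree lattice vectors
        lat = LatticeConstants()
        for m, n in [(3, 1), (7, 5), (12, 2)]:
            v = m * lat.a1 + n * lat.a2
            assert circumference(TubuleIndices(m, n)) == pytest.approx(
                float(np.linalg.norm(v))
            )

    def test_invalid_indices(self):
        with pytest.raises(InvalidGeometryError):
            TubuleIndices(0, 0)

    @given(st.integers(1, 30), st.integers(0, 30), st.integers(1, 30), st.integers(0, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_diameter_monotone_in_rollup_norm(self, m1, n1, m2, n2):
        a, b = TubuleIndices(m1, n1), TubuleIndices(m2, n2)
        na = m1 * m1 + m1 * n1 + n1 * n1
        nb = m2 * m2 + m2 * n2 + n2 * n2
        if na < nb:
            assert diameter(a) < diameter(b)


class TestIdealEmbedding:
    def test_triangle_count_and_edge_lengths(self):
        sheet = ideal_embedding(TubuleIndices(10, 0), rows=6)
        assert sheet.n_triangles == 2 * 10 * (6 - 1)
        for e in sheet.edges.values():
            ln = math.dist(sheet.positions[e.u], sheet.positions[e.v])
            assert ln == pytest.approx(1.0, abs=1e-8)

    def test_flat_limit_dihedrals(self):
        # large-m tubule approaches a flat sheet; deviation ~ 2*pi/m
        sheet = ideal_embedding(TubuleIndices(60, 0), rows=4)
        from helitube import dihedral_angle

        devs = [
            abs(dihedral_angle(sheet, eid) - math.pi) for eid in sheet.bound_edges
        ]
        assert max(devs) < 0.11

    def test_rows_validation(self):
        with pytest.raises(InvalidGeometryError):
            ideal_embedding(TubuleIndices(8, 0), rows=1)

    @pytest.mark.parametrize(
        "mn", [(10, 0), (9, 4), (8, 3), (5, 5), (3, 1), (14, 14), (12, 7)]
    )
    def test_classification_round_trip(self, mn):
        sheet = ideal_embedding(TubuleIndices(*mn), rows=5)
        assert classify_geometry(sheet) == TubuleIndices(*mn)

    def test_mirror_round_trip(self):
        sheet = ideal_embedding(TubuleIndices(4, 9), rows=5)
        mn, hand = classify_geometry_full(sheet)
        assert (mn, hand) == (TubuleIndices(9, 4), -1)


class TestIdealDihedrals:
    def test_type_consistency_and_signs(self):
        th = ideal_dihedrals(TubuleIndices(10, 0)).theta
        # the hoop-direction edge type is reflex (chord recessed below the
        # cylinder), the two cross types convex; all within (0, 2*pi)
        assert th[0] > math.pi
        assert th[1] < math.pi and th[2] < math.pi
        assert th[1] == pytest.approx(th[2], abs=1e-9)  # achiral symmetry
        assert all(0 < t < 2 * math.pi for t in th)

    def test_exact_ring_construction_oracle(self):
        # analytic equilateral (m,0) tube: rings of radius 1/(2 sin(pi/m))
        m = 10
        th = ideal_dihedrals(TubuleIndices(m, 0)).theta
        Rp = 1.0 / (2.0 * math.sin(math.pi / m))
        c = 2.0 * Rp * math.sin(math.pi / (2 * m))
        dz = math.sqrt(1.0 - c * c)

        def pos(i, j):
            phi = 2.0 * math.pi * (i + 0.5 * j) / m
            return (Rp * math.cos(phi), Rp * math.sin(phi), j * dz)

        from helitube.lattice import _dihedral

        hoop = _dihedral(pos(0, 1), pos(1, 1), pos(0, 2), pos(1, 0))
        assert th[0] == pytest.approx(hoop, abs=1e-9)

    def test_angle_gap_shrinks_with_diameter(self):
        gaps = []
        for m in (8, 9, 10):
            a = ideal_dihedrals(TubuleIndices(m, 0)).theta
            b = ideal_dihedrals(TubuleIndices(m + 1, 0)).theta
            gaps.append(sum(abs(x - y) for x, y in zip(a, b)))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_mirror_types_permuted(self):
        a = ideal_dihedrals(TubuleIndices(9, 4)).theta
        b = ideal_dihedrals(TubuleIndices(4, 9)).theta
        assert sorted(a) == pytest.approx(sorted(b), abs=1e-9)
        assert a != pytest.approx(b, abs=1e-9)


def test_relax_equilateral_recovers_unit_edges():
    # stretching-only relaxation restores all edge lengths of a perturbed
    # tubule, cross-checking the closed-form helical embedding
    from helitube.lattice import relax_equilateral

    sheet = ideal_embedding(TubuleIndices(6, 2), rows=4)
    rng = np.random.default_rng(5)
    for vid in sheet.positions:
        d = rng.normal(0, 0.01, 3)
        x = sheet.positions[vid]
        sheet.positions[vid] = (x[0] + d[0], x[1] + d[1], x[2] + d[2])
    relax_equilateral(sheet)
    for e in sheet.edges.values():
        assert math.dist(sheet.positions[e.u], sheet.positions[e.v]) == pytest.approx(
            1.0, abs=1e-8
        )


class TestBuildDisk:
    def test_single_monomer(self):
        d = build_disk(1)
        assert d.n_triangles == 1
        assert d.n_free_edges == 3

    def test_disk_topology(self):
        d = build_disk(4)
        assert d.euler_characteristic() == 1
        assert d.boundary_cycle_count() == 1

    @pytest.mark.parametrize("N", [50, 200])
    def test_isoperimetric_perimeter(self, N):
        # the lattice staircase boundary exceeds the smooth isoperimetric
        # perimeter 2*sqrt(pi*N*a0) by a bounded shape factor
        d = build_disk(N)
        perimeter = d.n_free_edges * 1.0
        expected = 2.0 * math.sqrt(math.pi * N * LatticeConstants().a0)
        assert 1.0 <= perimeter / expected < 1.3

    def test_bent_disk_positions_on_cylinder(self):
        mn = TubuleIndices(10, 0)
        d = build_disk(20, mn_target=mn)
        R = circumference(mn) / (2 * math.pi)
        for pos in d.positions.values():
            r = math.hypot(pos[0], pos[1])
            assert r == pytest.approx(R, rel=1e-6)
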