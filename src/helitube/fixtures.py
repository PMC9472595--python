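"""Deterministic structure fixtures mirroring the assembly outcome classes.

Each fixture satisfies the invariants of its declared category:
``ideal_tubule`` is defect-free, ``spiral_open`` never closed (overlapping
unfused boundary, the "toilet paper roll"), ``cracked_defective`` is a
closed tubule with a residual crack (extra boundary cycle), and
``bent_disk`` is a pre-closure patch at the target curvature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import LatticeConstants, TubuleIndices, build_disk, ideal_embedding
from .mesh import TriangulatedSheet

KINDS = ("ideal_tubule", "bent_disk", "spiral_open", "cracked_defective")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    mn: TubuleIndices = TubuleIndices(10, 0)
    size: int = 6  # rows for tubules, triangles for disks/spirals
    noise: float = 0.0  # vertex position noise sigma (l0)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def _apply_noise(sheet: TriangulatedSheet, sigma: float, seed: int):
    if sigma == 0.0:
        return
    rng = np.random.default_rng(seed)
    for vid in sorted(sheet.positions):
        d = rng.normal(0.0, sigma, 3)
        x = sheet.positions[vid]
        sheet.positions[vid] = (x[0] + d[0], x[1] + d[1], x[2] + d[2])


def make_fixture(spec: FixtureSpec, lat: LatticeConstants = LatticeConstants()):
    """Build the sheet described by ``spec`` (deterministic given its seed)."""
    mn = TubuleIndices(*spec.mn)
    if spec.kind == "ideal_tubule":
        sheet = ideal_embedding(mn, rows=max(3, spec.size), lat=lat)
    elif spec.kind == "bent_disk":
        sheet = build_disk(spec.size, mn_target=mn, lat=lat)
    elif spec.kind == "spiral_open":
        # a patch larger than one full turn, offset radially so the
        # overlapping boundary never fuses
        sheet = build_disk(spec.size, mn_target=mn, lat=lat, spiral_pitch=0.6 * lat.l0)
    elif spec.kind == "cracked_defective":
        sheet = ideal_embedding(mn, rows=max(4, spec.size), lat=lat)
        _open_crack(sheet)
    _apply_noise(sheet, spec.noise, spec.seed)
    return sheet


def _open_crack(sheet: TriangulatedSheet):
    """Remove one interior monomer, leaving a closed tube with a hole."""
    boundary = sheet.boundary_vertices()
    for tid, tri in sorted(sheet.triangles.items()):
        if not (set(tri) & boundary):
            _delete_triangle(sheet, tid)
            return
    raise ValueError("no interior monomer to remove; increase rows")


def _delete_triangle(sheet: TriangulatedSheet, tid):
    """Remove a triangle whose three edges are all bound (interior)."""
    for eid in sheet.tri_edges[tid]:
        sheet._detach(eid, tid)
        # the freed edge stays with its other triangle
    for v in sheet.triangles[tid]:
        sheet.vertex_tris[v].discard(tid)
        sheet._dirty_around(v)
    del sheet.triangles[tid], sheet.tri_parity[tid], sheet.tri_edges[tid]
    del sheet._tri_bound[tid]
    sheet._one_bond_tris.discard(tid)


class _StaticTraj:
    """Minimal trajectory-like wrapper so fixtures feed classify_outcome."""

    def __init__(self, sheet, closed, N_close=None, seed=0):
        self.sheet = sheet
        self.closed = closed
        self.N_close = N_close
        self.finished = True
        self.seed = seed


def fixture_trajectory(spec: FixtureSpec):
    """Fixture wrapped as a finished trajectory record."""
    sheet = make_fixture(spec)
    closed = spec.kind in ("ideal_tubule", "cracked_defective")
    N_close = sheet.n_triangles if closed else None
    return _StaticTraj(sheet, closed, N_close, seed=spec.seed)
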