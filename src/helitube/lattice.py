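"""Triangular-lattice and tubule geometry.

A helical tubule is a triangular lattice rolled onto a cylinder so that the
lattice point ``m*a1 + n*a2`` coincides with the origin (the carbon-nanotube
rollup convention).  ``m`` counts lattice sites around one turn of the helix,
``n`` sites in the orthogonal direction; ``n = 0`` tubules are achiral.  The
rollup vector fixes the circumference ``|C| = l0*sqrt(m^2 + m*n + n^2)``, the
diameter ``D = |C|/pi`` and, through an explicit equilateral embedding, the
three ideal dihedral angles (one per edge type) that parameterise the monomer
Hamiltonian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize, root

from .mesh import LATTICE_STEPS, SLOT_PAIRS, MeshError, TriangulatedSheet

SQRT3 = math.sqrt(3.0)


class InvalidGeometryError(ValueError):
    """Invalid tubule rollup indices."""


class RelaxationError(RuntimeError):
    """Equilateral relaxation of an ideal embedding failed to converge."""


@dataclass(frozen=True)
class LatticeConstants:
    """Stress-free lattice geometry.

    ``l0`` is the stress-free edge length (the length unit); the monomer area
    is ``a0 = (sqrt(3)/4) l0**2``.  The unit lattice vectors ``a1``, ``a2``
    are separated by 60 degrees.
    """

    l0: float = 1.0

    def __post_init__(self):
        if self.l0 <= 0:
            raise InvalidGeometryError("l0 must be positive")

    @property
    def a0(self) -> float:
        return SQRT3 / 4.0 * self.l0**2

    @property
    def a1(self):
        return np.array([self.l0, 0.0])

    @property
    def a2(self):
        return np.array([0.5 * self.l0, SQRT3 / 2.0 * self.l0])


@dataclass(frozen=True, order=True)
class TubuleIndices:
    """Rollup indices (m, n) naming a tubule geometry; m >= 1, n >= 0.

    Chirality: for ``n > 0`` the index names one handedness; the mirror
    structure carries the same canonical ``(m, n)`` with ``handedness = -1``
    wherever a handedness is reported.
    """

    m: int
    n: int = 0

    def __post_init__(self):
        if self.m < 1 or self.n < 0:
            raise InvalidGeometryError(f"invalid tubule indices ({self.m},{self.n})")

    def __iter__(self):
        return iter((self.m, self.n))

    def __str__(self):
        return f"({self.m},{self.n})"


@dataclass(frozen=True)
class IdealAngles:
    """Ideal dihedral angles (radians), one per edge type, for one geometry.

    Flat sheet corresponds to all angles equal to pi; an outward-bulging
    (convex) tubule has angles below pi.
    """

    theta: tuple[float, float, float]
    mn: TubuleIndices

    def __getitem__(self, etype: int) -> float:
        """Angle for edge type 1, 2 or 3."""
        return self.theta[etype - 1]


def circumference(mn: TubuleIndices, lat: LatticeConstants = LatticeConstants()) -> float:
    """Norm of the rollup vector m*a1 + n*a2."""
    m, n = mn
    return lat.l0 * math.sqrt(m * m + m * n + n * n)


def diameter(mn: TubuleIndices, lat: LatticeConstants = LatticeConstants()) -> float:
    """Tubule diameter D = |C| / pi."""
    return circumference(mn, lat) / math.pi


# --------------------------------------------------------------------------
# ideal embeddings
# --------------------------------------------------------------------------

def _rollup_frame(mn, lat):
    m, n = mn
    C = m * lat.a1 + n * lat.a2
    Cn = float(np.linalg.norm(C))
    chat = C / Cn
    that = np.array([-chat[1], chat[0]])
    return Cn, chat, that


def _lattice_points(lat):
    A = np.column_stack([lat.a1, lat.a2])
    return A


def helical_parameters(mn: TubuleIndices, lat: LatticeConstants = LatticeConstants()):
    """Exact equilateral helical embedding parameters (rho, a1, a2, h1, h2).

    The lattice point (i, j) maps to the cylinder point at angle
    ``i*alpha1 + j*alpha2``, height ``i*h1 + j*h2`` and radius ``rho``; the
    five parameters solve the three unit-edge-length conditions plus the two
    rollup closure conditions ``m*alpha1 + n*alpha2 = 2*pi`` and
    ``m*h1 + n*h2 = 0``.
    """
    mn = TubuleIndices(*mn)
    m, n = mn
    Cn, chat, that = _rollup_frame(mn, lat)
    l02 = lat.l0 * lat.l0
    x0 = np.array(
        [
            Cn / (2.0 * math.pi),
            2.0 * math.pi * float(chat @ lat.a1) / Cn,
            2.0 * math.pi * float(chat @ lat.a2) / Cn,
            float(that @ lat.a1),
            float(that @ lat.a2),
        ]
    )

    def eqs(x):
        rho, al1, al2, h1, h2 = x
        return [
            2 * rho * rho * (1 - math.cos(al1)) + h1 * h1 - l02,
            2 * rho * rho * (1 - math.cos(al2)) + h2 * h2 - l02,
            2 * rho * rho * (1 - math.cos(al2 - al1)) + (h2 - h1) ** 2 - l02,
            m * al1 + n * al2 - 2.0 * math.pi,
            m * h1 + n * h2,
        ]

    sol = root(eqs, x0, tol=1e-13)
    resid = max(abs(r) for r in eqs(sol.x))
    if resid > 1e-10 * l02:
        raise RelaxationError(
            f"helical embedding for {mn} did not converge (residual {resid:.2e})"
        )
    return tuple(float(v) for v in sol.x)


def ideal_embedding(
    mn: TubuleIndices,
    rows: int = 6,
    lat: LatticeConstants = LatticeConstants(),
    length_tol: float = 1e-8,
) -> TriangulatedSheet:
    """Closed cylindrical mesh of the (m, n) tubule with all edges at l0.

    Vertices are placed by the exact helically symmetric equilateral
    embedding (:func:`helical_parameters`), so every edge length equals
    ``l0`` to solver precision (verified against ``length_tol * l0``).
    ``rows`` counts vertex levels along the axis; the (m, 0) tubule then has
    ``2*m*(rows-1)`` triangles.
    """
    mn = TubuleIndices(*mn)
    if rows < 2:
        raise InvalidGeometryError("rows must be >= 2")
    m, n = mn
    Cn, chat, that = _rollup_frame(mn, lat)
    A = _lattice_points(lat)
    H = (rows - 1) * lat.l0 * SQRT3 / 2.0
    tol = 1e-9 * lat.l0
    rho, al1, al2, h1, h2 = helical_parameters(mn, lat)

    # integer search window covering s in [-l0, Cn + l0], z in [-tol, H + tol]
    Q = np.column_stack([chat, that])  # (s, z) = Q.T @ p ; p = A @ (i, j)
    Minv = np.linalg.inv(Q.T @ A)
    corners = [
        Minv @ np.array([s, z])
        for s in (-1.5 * lat.l0, Cn + 1.5 * lat.l0)
        for z in (-1.5 * lat.l0, H + 1.5 * lat.l0)
    ]
    lo = np.floor(np.min(corners, axis=0)).astype(int) - 2
    hi = np.ceil(np.max(corners, axis=0)).astype(int) + 2

    def sz(i, j):
        p = A @ (i, j)
        return float(chat @ p), float(that @ p)

    def canon(i, j):
        s, _ = sz(i, j)
        k = math.floor((s + tol) / Cn)
        return (i - k * m, j - k * n)

    keep = {}
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            key = canon(i, j)
            if key in keep:
                continue
            s, z = sz(*key)
            if -tol <= z <= H + tol:
                keep[key] = (s, z)

    verts = []
    vindex = {}
    for key in keep:
        i, j = key
        phi = i * al1 + j * al2
        vindex[key] = len(verts)
        verts.append((rho * math.cos(phi), rho * math.sin(phi), i * h1 + j * h2))

    tris = []
    seen = set()
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for parity, corners3 in (
                (0, ((i, j), (i + 1, j), (i, j + 1))),
                (1, ((i + 1, j), (i + 1, j + 1), (i, j + 1))),
            ):
                keys = tuple(canon(*c) for c in corners3)
                if not all(k in keep for k in keys):
                    continue
                tkey = tuple(sorted(keys))
                if tkey in seen:
                    continue
                seen.add(tkey)
                tris.append((tuple(vindex[k] for k in keys), parity))

    sheet = TriangulatedSheet.from_triangles(verts, tris)
    worst = 0.0
    pos = sheet.positions
    for e in sheet.edges.values():
        pu, pv = pos[e.u], pos[e.v]
        ln = math.dist(pu, pv)
        worst = max(worst, abs(ln - lat.l0))
    if worst > length_tol * lat.l0:
        raise RelaxationError(
            f"embedding edge-length residual {worst:.3e} l0 for {mn}"
        )
    return sheet


def relax_equilateral(sheet, l0=1.0, length_tol=1e-8):
    """Minimise total stretching energy at fixed topology (in place)."""
    vids = sorted(sheet.positions)
    vmap = {v: i for i, v in enumerate(vids)}
    x0 = np.array([sheet.positions[v] for v in vids], dtype=float)
    eu = np.array([vmap[sheet.edges[e].u] for e in sheet.edges])
    ev = np.array([vmap[sheet.edges[e].v] for e in sheet.edges])

    def fg(x):
        pts = x.reshape(-1, 3)
        d = pts[eu] - pts[ev]
        ln = np.sqrt((d * d).sum(axis=1))
        r = ln - l0
        f = float((r * r).sum())
        g = np.zeros_like(pts)
        coef = (2.0 * r / ln)[:, None] * d
        np.add.at(g, eu, coef)
        np.add.at(g, ev, -coef)
        return f, g.ravel()

    res = minimize(
        fg,
        x0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 20000, "maxfun": 100000, "ftol": 1e-18, "gtol": 1e-13},
    )
    pts = res.x.reshape(-1, 3)
    d = pts[eu] - pts[ev]
    ln = np.sqrt((d * d).sum(axis=1))
    worst = float(np.abs(ln - l0).max())
    if worst > length_tol * l0:
        raise RelaxationError(
            f"edge-length residual {worst:.3e} l0 exceeds {length_tol:.1e} l0 "
            f"(gradient norm {np.linalg.norm(res.jac):.3e})"
        )
    for v, i in vmap.items():
        sheet.positions[v] = tuple(pts[i])


# --------------------------------------------------------------------------
# ideal dihedral angles
# --------------------------------------------------------------------------

def dihedral_angle(sheet: TriangulatedSheet, eid: int) -> float:
    """Interior dihedral angle at a bound edge, measured through the material.

    A flat pair of triangles gives pi; a convex (outward-bulging) fold gives
    an angle below pi.  Range (0, 2*pi).
    """
    e = sheet.edges[eid]
    if not e.bound:
        raise MeshError("dihedral undefined on a free edge")
    t1, t2 = e.tris
    u, v = sheet.directed(eid, t1)
    w1 = sheet.apex_of(t1, eid)
    w2 = sheet.apex_of(t2, eid)
    pu, pv = sheet.positions[u], sheet.positions[v]
    p1, p2 = sheet.positions[w1], sheet.positions[w2]
    return _dihedral(pu, pv, p1, p2)


def _dihedral(pu, pv, p1, p2):
    ex, ey, ez = pv[0] - pu[0], pv[1] - pu[1], pv[2] - pu[2]
    ax, ay, az = p1[0] - pu[0], p1[1] - pu[1], p1[2] - pu[2]
    bx, by, bz = p2[0] - pv[0], p2[1] - pv[1], p2[2] - pv[2]
    # n1 = e x a ; n2 = (-e) x b
    n1x, n1y, n1z = ey * az - ez * ay, ez * ax - ex * az, ex * ay - ey * ax
    n2x, n2y, n2z = by * ez - bz * ey, bz * ex - bx * ez, bx * ey - by * ex
    l1 = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    l2 = math.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    el = math.sqrt(ex * ex + ey * ey + ez * ez)
    if l1 == 0.0 or l2 == 0.0 or el == 0.0:
        raise MeshError("degenerate triangle: dihedral undefined")
    cx, cy, cz = (
        n1y * n2z - n1z * n2y,
        n1z * n2x - n1x * n2z,
        n1x * n2y - n1y * n2x,
    )
    sinphi = (cx * ex + cy * ey + cz * ez) / (l1 * l2 * el)
    cosphi = (n1x * n2x + n1y * n2y + n1z * n2z) / (l1 * l2)
    return math.pi - math.atan2(sinphi, cosphi)


@lru_cache(maxsize=256)
def _ideal_dihedrals_cached(m, n, rows, l0):
    mn = TubuleIndices(m, n)
    lat = LatticeConstants(l0)
    sheet = ideal_embedding(mn, rows=rows, lat=lat)
    boundary = sheet.boundary_vertices()
    per_type = {1: [], 2: [], 3: []}
    for eid in sheet.bound_edges:
        e = sheet.edges[eid]
        t1, t2 = e.tris
        vs = set(sheet.triangles[t1]) | set(sheet.triangles[t2])
        if vs & boundary:
            continue
        per_type[e.etype].append(dihedral_angle(sheet, eid))
    out = []
    for t in (1, 2, 3):
        vals = per_type[t]
        if not vals:
            raise InvalidGeometryError(
                f"no interior edge of type {t}; increase rows (got {rows})"
            )
        if max(vals) - min(vals) > 1e-6:
            raise RelaxationError(
                f"type-{t} dihedrals spread {max(vals) - min(vals):.2e} rad; "
                "helical symmetry violated (relaxation not converged?)"
            )
        out.append(sum(vals) / len(vals))
    return IdealAngles(theta=tuple(out), mn=mn)


def ideal_dihedrals(
    mn: TubuleIndices, rows: int = 8, lat: LatticeConstants = LatticeConstants()
) -> IdealAngles:
    """Ideal dihedral-angle triple of the (m, n) tubule.

    Measured on interior edges of a relaxed ideal embedding; by helical
    symmetry all interior edges of one type agree (enforced to 1e-6 rad).
    """
    m, n = mn
    return _ideal_dihedrals_cached(m, n, rows, lat.l0)


# --------------------------------------------------------------------------
# disks
# --------------------------------------------------------------------------

def build_disk(
    N: int,
    mn_target: TubuleIndices | None = None,
    lat: LatticeConstants = LatticeConstants(),
    spiral_pitch: float = 0.0,
) -> TriangulatedSheet:
    """Roughly circular N-triangle patch of the lattice.

    With ``mn_target`` the patch is bent to the target tubule's stress-free
    curvature by rolling the unrolled coordinates onto the target cylinder
    (without seam identification, so patches wider than the circumference
    overlap; a positive ``spiral_pitch`` then offsets successive turns
    radially, producing an open spiral).
    """
    if N < 1:
        raise InvalidGeometryError("N must be >= 1")
    A = _lattice_points(lat)

    def centroid(cell):
        (i, j), parity = cell
        if parity == 0:
            pts = ((i, j), (i + 1, j), (i, j + 1))
        else:
            pts = ((i + 1, j), (i + 1, j + 1), (i, j + 1))
        c = sum(np.array(A @ p) for p in pts) / 3.0
        return c

    # greedy edge-connected growth by centroid radius keeps the patch simply
    # connected and roughly circular
    import heapq

    start = ((0, 0), 0)
    chosen = []
    chosen_set = set()
    heap = [(float(np.linalg.norm(centroid(start))), start)]
    in_heap = {start}
    while heap and len(chosen) < N:
        _, cell = heapq.heappop(heap)
        if cell in chosen_set:
            continue
        chosen.append(cell)
        chosen_set.add(cell)
        (i, j), parity = cell
        if parity == 0:
            nbrs = [((i, j), 1), ((i - 1, j), 1), ((i, j - 1), 1)]
        else:
            nbrs = [((i, j), 0), ((i + 1, j), 0), ((i, j + 1), 0)]
        for nb in nbrs:
            if nb not in chosen_set and nb not in in_heap:
                in_heap.add(nb)
                heapq.heappush(heap, (float(np.linalg.norm(centroid(nb))), nb))

    # collect vertices
    vindex = {}
    verts2d = []
    tris = []
    for (i, j), parity in chosen:
        if parity == 0:
            keys = ((i, j), (i + 1, j), (i, j + 1))
        else:
            keys = ((i + 1, j), (i + 1, j + 1), (i, j + 1))
        idx = []
        for k in keys:
            if k not in vindex:
                vindex[k] = len(verts2d)
                verts2d.append(A @ k)
            idx.append(vindex[k])
        tris.append((tuple(idx), parity))

    if mn_target is None:
        verts = [(float(p[0]), float(p[1]), 0.0) for p in verts2d]
    else:
        mn_target = TubuleIndices(*mn_target)
        Cn, chat, that = _rollup_frame(mn_target, lat)
        R = Cn / (2.0 * math.pi)
        verts = []
        for p in verts2d:
            s = float(chat @ p)
            z = float(that @ p)
            phi = 2.0 * math.pi * s / Cn
            r = R + spiral_pitch * phi / (2.0 * math.pi)
            verts.append((r * math.cos(phi), r * math.sin(phi), z))
    return TriangulatedSheet.from_triangles(verts, tris)
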