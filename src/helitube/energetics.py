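"""The monomer Hamiltonian: edge stretching, dihedral bending, edge binding.

Energies are in units of k_B*T.  Per bound edge pair the binding term
contributes ``-E_B``; bending is harmonic in the dihedral-angle deviation,
``(B/2)(theta_i - theta0_i)**2`` with the preferred angle ``theta0_i`` set by
the edge type ``i`` of the target tubule geometry; stretching is harmonic in
the edge length, ``(k_S/2)(l_j - l0)**2`` for every edge.  The harmonic 1/2
prefactors are the package's convention and are used consistently everywhere,
including the per-monomer bending term ``(B/4) sum_i dtheta_i**2`` of the
equilibrium models (each bound edge is shared by two monomers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .lattice import IdealAngles, TubuleIndices, _dihedral, ideal_dihedrals
from .mesh import TriangulatedSheet


@dataclass(frozen=True)
class EnergyParams:
    """Hamiltonian constants (all in k_B*T, lengths in l0)."""

    theta0: IdealAngles | tuple[float, float, float]
    E_B: float = 6.0
    B: float = 20.0
    k_S: float = 200.0
    l0: float = 1.0

    def __post_init__(self):
        if self.E_B < 0 or self.B < 0 or self.k_S <= 0 or self.l0 <= 0:
            raise ValueError("require E_B >= 0, B >= 0, k_S > 0, l0 > 0")
        if not isinstance(self.theta0, IdealAngles):
            t = tuple(float(x) for x in self.theta0)
            if len(t) != 3:
                raise ValueError("theta0 must have one angle per edge type")
            object.__setattr__(self, "theta0", IdealAngles(theta=t, mn=None))

    @classmethod
    def for_target(cls, mn: TubuleIndices, **kw) -> "EnergyParams":
        """Parameters with theta0 set to the ideal angles of target (m, n)."""
        return cls(theta0=ideal_dihedrals(TubuleIndices(*mn)), **kw)

    def with_(self, **kw) -> "EnergyParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class EnergyBreakdown:
    E_stretch: float
    E_bend: float
    E_bind: float

    @property
    def E_total(self) -> float:
        return self.E_stretch + self.E_bend + self.E_bind


def total_energy(sheet: TriangulatedSheet, p: EnergyParams) -> EnergyBreakdown:
    """Full Hamiltonian evaluation over the sheet."""
    ks2 = 0.5 * p.k_S
    b2 = 0.5 * p.B
    pos = sheet.positions
    es = 0.0
    for e in sheet.edges.values():
        pu, pv = pos[e.u], pos[e.v]
        dx, dy, dz = pu[0] - pv[0], pu[1] - pv[1], pu[2] - pv[2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz) - p.l0
        es += ks2 * r * r
    eb = 0.0
    nb = 0
    for eid in sheet.bound_edges:
        e = sheet.edges[eid]
        d = _edge_dihedral(sheet, eid)
        dd = d - p.theta0[e.etype]
        eb += b2 * dd * dd
        nb += 1
    return EnergyBreakdown(E_stretch=es, E_bend=eb, E_bind=-p.E_B * nb)


def _edge_dihedral(sheet, eid):
    e = sheet.edges[eid]
    t1 = e.tris[0]
    u, v = sheet.directed(eid, t1)
    w1 = sheet.apex_of(t1, eid)
    w2 = sheet.apex_of(e.tris[1], eid)
    pos = sheet.positions
    return _dihedral(pos[u], pos[v], pos[w1], pos[w2])


def _stretch(pos_u, pos_v, ks2, l0):
    dx = pos_u[0] - pos_v[0]
    dy = pos_u[1] - pos_v[1]
    dz = pos_u[2] - pos_v[2]
    r = math.sqrt(dx * dx + dy * dy + dz * dz) - l0
    return ks2 * r * r


def vertex_region_edges(sheet, vids):
    """(stretch-edge ids, bend-edge ids) whose energy depends on ``vids``."""
    if not isinstance(vids, (set, frozenset)):
        vids = set(vids)
    stretch = set()
    bend = set()
    for v in vids:
        stretch |= sheet.vertex_edges[v]
        for t in sheet.vertex_tris[v]:
            for eid in sheet.tri_edges[t]:
                if sheet.edges[eid].bound:
                    bend.add(eid)
    return stretch, bend


def region_energy(sheet: TriangulatedSheet, vids, p: EnergyParams) -> float:
    """Stretch + bend + bind over the neighborhood of the given vertices.

    Contains every term of the Hamiltonian that can change when exactly these
    vertices move or when edges between them change binding state, so the
    difference of two region evaluations equals the full energy difference.
    """
    stretch, bend = vertex_region_edges(sheet, vids)
    ks2 = 0.5 * p.k_S
    b2 = 0.5 * p.B
    pos = sheet.positions
    etot = 0.0
    for eid in stretch:
        e = sheet.edges[eid]
        etot += _stretch(pos[e.u], pos[e.v], ks2, p.l0)
    for eid in bend:
        e = sheet.edges[eid]
        dd = _edge_dihedral(sheet, eid) - p.theta0[e.etype]
        etot += b2 * dd * dd - p.E_B
    return etot


def vertex_move_delta(sheet, vid, new_pos, p: EnergyParams) -> float:
    """Energy change of displacing one vertex (no mutation)."""
    pos = sheet.positions
    old = pos[vid]
    stretch, bend = vertex_region_edges(sheet, (vid,))
    before = 0.0
    ks2 = 0.5 * p.k_S
    b2 = 0.5 * p.B
    for eid in stretch:
        e = sheet.edges[eid]
        before += _stretch(pos[e.u], pos[e.v], ks2, p.l0)
    for eid in bend:
        e = sheet.edges[eid]
        dd = _edge_dihedral(sheet, eid) - p.theta0[e.etype]
        before += b2 * dd * dd
    pos[vid] = tuple(new_pos)
    after = 0.0
    for eid in stretch:
        e = sheet.edges[eid]
        after += _stretch(pos[e.u], pos[e.v], ks2, p.l0)
    for eid in bend:
        e = sheet.edges[eid]
        dd = _edge_dihedral(sheet, eid) - p.theta0[e.etype]
        after += b2 * dd * dd
    pos[vid] = old
    return after - before


def insertion_delta(sheet, eid, apex_pos, p: EnergyParams) -> float:
    """Energy change of binding a new monomer across free edge ``eid``."""
    e = sheet.edges[eid]
    t1 = e.tris[0]
    u, v = sheet.directed(eid, t1)
    w1 = sheet.apex_of(t1, eid)
    pos = sheet.positions
    ks2 = 0.5 * p.k_S
    de = _stretch(pos[u], apex_pos, ks2, p.l0) + _stretch(pos[v], apex_pos, ks2, p.l0)
    theta = _dihedral(pos[u], pos[v], pos[w1], apex_pos)
    dd = theta - p.theta0[e.etype]
    return de + 0.5 * p.B * dd * dd - p.E_B


def deletion_delta(sheet, tid, p: EnergyParams) -> float:
    """Energy change of removing a one-bond monomer (negative insertion)."""
    beid = sheet._bound_edge_of(tid)
    apex = sheet.apex_of(tid, beid)
    e = sheet.edges[beid]
    tother = e.tris[0] if e.tris[0] != tid else e.tris[1]
    u, v = sheet.directed(beid, tother)
    w1 = sheet.apex_of(tother, beid)
    pos = sheet.positions
    ks2 = 0.5 * p.k_S
    de = _stretch(pos[u], pos[apex], ks2, p.l0) + _stretch(pos[v], pos[apex], ks2, p.l0)
    theta = _dihedral(pos[u], pos[v], pos[w1], pos[apex])
    dd = theta - p.theta0[e.etype]
    return -(de + 0.5 * p.B * dd * dd - p.E_B)


class NeighborhoodCache:
    """Caches the topological neighborhood used by vertex-move deltas.

    The stretch/bend term lists of a vertex depend only on mesh topology,
    which changes rarely compared with vertex moves; the cache is invalidated
    wholesale via the sheet's ``topo_gen`` counter.
    """

    __slots__ = ("sheet", "p", "_gen", "_cache", "_ks2", "_b2")

    def __init__(self, sheet: TriangulatedSheet, p: EnergyParams):
        self.sheet = sheet
        self.p = p
        self._gen = -1
        self._cache = {}
        self._ks2 = 0.5 * p.k_S
        self._b2 = 0.5 * p.B

    def _build(self, vid):
        sheet, p = self.sheet, self.p
        stretch = tuple(
            (self.sheet.edges[eid].u, self.sheet.edges[eid].v)
            for eid in sheet.vertex_edges[vid]
        )
        bend = []
        seen = set()
        for t in sheet.vertex_tris[vid]:
            for eid in sheet.tri_edges[t]:
                if eid in seen:
                    continue
                seen.add(eid)
                e = sheet.edges[eid]
                if e.bound:
                    t1 = e.tris[0]
                    u, v = sheet.directed(eid, t1)
                    w1 = sheet.apex_of(t1, eid)
                    w2 = sheet.apex_of(e.tris[1], eid)
                    bend.append((u, v, w1, w2, p.theta0[e.etype]))
        return stretch, tuple(bend)

    def _local(self, nb, vid, pos_vid):
        pos = self.sheet.positions
        old = pos[vid]
        pos[vid] = pos_vid
        ks2, b2, l0 = self._ks2, self._b2, self.p.l0
        stretch, bend = nb
        sqrt, atan2 = math.sqrt, math.atan2
        pi = math.pi
        etot = 0.0
        for u, v in stretch:
            pu, pv = pos[u], pos[v]
            dx = pu[0] - pv[0]
            dy = pu[1] - pv[1]
            dz = pu[2] - pv[2]
            r = sqrt(dx * dx + dy * dy + dz * dz) - l0
            etot += ks2 * r * r
        for u, v, w1, w2, th0 in bend:
            pu, pv, p1, p2 = pos[u], pos[v], pos[w1], pos[w2]
            ex, ey, ez = pv[0] - pu[0], pv[1] - pu[1], pv[2] - pu[2]
            ax, ay, az = p1[0] - pu[0], p1[1] - pu[1], p1[2] - pu[2]
            bx, by, bz = p2[0] - pv[0], p2[1] - pv[1], p2[2] - pv[2]
            n1x, n1y, n1z = ey * az - ez * ay, ez * ax - ex * az, ex * ay - ey * ax
            n2x, n2y, n2z = by * ez - bz * ey, bz * ex - bx * ez, bx * ey - by * ex
            l1 = sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
            l2 = sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
            el = sqrt(ex * ex + ey * ey + ez * ez)
            cxx = n1y * n2z - n1z * n2y
            cyy = n1z * n2x - n1x * n2z
            czz = n1x * n2y - n1y * n2x
            sinphi = (cxx * ex + cyy * ey + czz * ez) / (l1 * l2 * el)
            cosphi = (n1x * n2x + n1y * n2y + n1z * n2z) / (l1 * l2)
            dd = pi - atan2(sinphi, cosphi) - th0
            etot += b2 * dd * dd
        pos[vid] = old
        return etot

    def delta(self, vid, new_pos):
        """Energy change of moving ``vid`` to ``new_pos`` (no mutation)."""
        dirty = self.sheet.dirty_vertices
        if dirty:
            cache = self._cache
            for v in dirty:
                cache.pop(v, None)
            dirty.clear()
        nb = self._cache.get(vid)
        if nb is None:
            nb = self._build(vid)
            self._cache[vid] = nb
        old = self.sheet.positions[vid]
        return self._local(nb, vid, new_pos) - self._local(nb, vid, old)


def energy_delta(sheet, move, p: EnergyParams) -> float:
    """Incremental energy change of a move proposal.

    ``move`` is one of
      ("vertex", vid, new_pos) | ("insert", eid, apex_pos) | ("delete", tid)
    and the result equals total_energy(after) - total_energy(before).
    """
    kind = move[0]
    if kind == "vertex":
        return vertex_move_delta(sheet, move[1], move[2], p)
    if kind == "insert":
        return insertion_delta(sheet, move[1], move[2], p)
    if kind == "delete":
        return deletion_delta(sheet, move[1], p)
    raise ValueError(f"unknown move kind {kind!r}")
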