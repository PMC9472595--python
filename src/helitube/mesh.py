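"""Dynamic triangulated sheet with typed edges.

The sheet is the assembling structure: an oriented triangular mesh in 3-space
whose triangles are monomers.  Every triangle carries one edge of each type
(1, 2, 3); an edge is *bound* when shared by two triangles and *free* when it
lies on the boundary.  Triangles carry a sublattice parity ("up"/"down" in the
underlying triangular lattice); bound edges always join triangles of opposite
parity, which keeps intrinsic lattice coordinates well defined and makes the
tubule rollup indices measurable from topology alone.

The mutating operations (monomer insertion/removal, edge fusion/fission) are
exact inverses of each other, which the Monte Carlo engine relies on both for
detailed balance and for rolling back rejected proposals.
"""

from __future__ import annotations

import math
from collections import deque

from .util import IndexedSet

#: edge types by triangle parity for vertex slots (AB, BC, CA); parity 0 is an
#: "up" lattice triangle, parity 1 a "down" one.
EDGE_TYPES = ((1, 3, 2), (2, 1, 3))

#: vertex index pairs of the three edge slots of a triangle (A,B,C).
SLOT_PAIRS = ((0, 1), (1, 2), (2, 0))

#: intrinsic lattice step (units of the lattice vectors a1, a2) taken by each
#: directed slot edge, by parity.  Up triangle: A=(i,j), B=(i+1,j), C=(i,j+1);
#: down triangle: A=(i+1,j), B=(i+1,j+1), C=(i,j+1).
LATTICE_STEPS = (
    ((1, 0), (-1, 1), (0, -1)),
    ((0, 1), (-1, 0), (1, -1)),
)


class MeshError(ValueError):
    """Inconsistent or unsupported mesh operation."""


class NotClosedError(MeshError):
    """Raised when a closed (cylindrical) topology is required but absent."""


class Edge:
    __slots__ = ("u", "v", "etype", "tris")

    def __init__(self, u, v, etype, tris):
        self.u = u
        self.v = v
        self.etype = etype
        self.tris = tris  # list of triangle ids; tris[0] owns the (u->v) direction

    @property
    def bound(self):
        return len(self.tris) == 2


class TriangulatedSheet:
    """Oriented triangular mesh with typed edges and O(1) boundary sampling."""

    def __init__(self):
        self.positions = {}  # vid -> (x, y, z)
        self.vertex_ids = IndexedSet()  # for O(1) uniform vertex sampling
        self.triangles = {}  # tid -> (a, b, c) counter-clockwise
        self.tri_parity = {}  # tid -> 0 | 1
        self.tri_edges = {}  # tid -> (eid_AB, eid_BC, eid_CA)
        self.edges = {}  # eid -> Edge
        self.vertex_tris = {}  # vid -> set of tids
        self.vertex_edges = {}  # vid -> set of eids
        self.free_edges = IndexedSet()
        self.bound_edges = IndexedSet()
        self._one_bond_tris = set()
        self._tri_bound = {}  # tid -> number of bound edges
        self.topo_gen = 0  # bumped on every topology change
        self.dirty_vertices = set()  # vertices whose energy neighborhood changed
        self._vnext = 0
        self._enext = 0
        self._tnext = 0

    # ------------------------------------------------------------------ sizes
    @property
    def n_vertices(self):
        return len(self.positions)

    @property
    def n_triangles(self):
        return len(self.triangles)

    @property
    def n_bound_edges(self):
        return len(self.bound_edges)

    @property
    def n_free_edges(self):
        return len(self.free_edges)

    # ------------------------------------------------------------- primitives
    def _new_vertex(self, pos):
        vid = self._vnext
        self._vnext += 1
        self.positions[vid] = tuple(pos)
        self.vertex_ids.add(vid)
        self.vertex_tris[vid] = set()
        self.vertex_edges[vid] = set()
        return vid

    def _new_edge(self, u, v, etype, tid):
        self.topo_gen += 1
        eid = self._enext
        self._enext += 1
        self.edges[eid] = Edge(u, v, etype, [tid])
        self.vertex_edges[u].add(eid)
        self.vertex_edges[v].add(eid)
        self.free_edges.add(eid)
        return eid

    def _set_tri_bound(self, tid, count):
        self._tri_bound[tid] = count
        if count == 1:
            self._one_bond_tris.add(tid)
        else:
            self._one_bond_tris.discard(tid)

    def _attach(self, eid, tid):
        """Second triangle arrives at an edge: free -> bound."""
        self.topo_gen += 1
        e = self.edges[eid]
        e.tris.append(tid)
        self.free_edges.discard(eid)
        self.bound_edges.add(eid)
        for t in e.tris:
            self._set_tri_bound(t, self._tri_bound[t] + 1)
        # both triangles got +1, but _set_tri_bound was called with stale value
        # for the first one; recompute cleanly:
        # (loop above already incremented each once, so counts are correct)

    def _detach(self, eid, tid):
        """Remove ``tid`` from a bound edge: bound -> free."""
        self.topo_gen += 1
        e = self.edges[eid]
        e.tris.remove(tid)
        self.bound_edges.discard(eid)
        self.free_edges.add(eid)
        self._set_tri_bound(tid, self._tri_bound[tid] - 1)
        self._set_tri_bound(e.tris[0], self._tri_bound[e.tris[0]] - 1)

    def _dirty_around(self, v):
        """Mark every vertex whose energy neighborhood may involve ``v``."""
        D = self.dirty_vertices
        D.add(v)
        for t in self.vertex_tris.get(v, ()):
            for eid in self.tri_edges[t]:
                for t2 in self.edges[eid].tris:
                    a, b, c = self.triangles[t2]
                    D.add(a)
                    D.add(b)
                    D.add(c)

    def directed(self, eid, tid=None):
        """The (u, v) traversal of edge ``eid`` in triangle ``tid`` (default:
        the owning triangle ``tris[0]``)."""
        e = self.edges[eid]
        if tid is None:
            tid = e.tris[0]
        tri = self.triangles[tid]
        slot = self.tri_edges[tid].index(eid)
        i, j = SLOT_PAIRS[slot]
        return tri[i], tri[j]

    def apex_of(self, tid, eid):
        """Vertex of ``tid`` not on edge ``eid``."""
        e = self.edges[eid]
        for v in self.triangles[tid]:
            if v != e.u and v != e.v:
                return v
        raise MeshError("degenerate triangle")

    # ----------------------------------------------------------- construction
    @classmethod
    def from_triangles(cls, points, tris):
        """Build a sheet from shared-vertex triangle soup.

        Parameters
        ----------
        points : sequence of (x, y, z)
        tris : sequence of ((a, b, c), parity) with CCW vertex index triples.
        """
        sheet = cls()
        vids = [sheet._new_vertex(p) for p in points]
        open_edges = {}  # (min,max) -> eid, only while free
        for (a, b, c), parity in tris:
            sheet._add_triangle_shared((vids[a], vids[b], vids[c]), parity, open_edges)
        return sheet

    def _add_triangle_shared(self, verts, parity, open_edges):
        tid = self._tnext
        self._tnext += 1
        self.triangles[tid] = tuple(verts)
        self.tri_parity[tid] = parity
        self._tri_bound[tid] = 0
        eids = []
        for slot, (i, j) in enumerate(SLOT_PAIRS):
            u, v = verts[i], verts[j]
            etype = EDGE_TYPES[parity][slot]
            key = (u, v) if u < v else (v, u)
            eid = open_edges.pop(key, None)
            if eid is None:
                eid = self._new_edge(u, v, etype, tid)
                open_edges[key] = eid
            else:
                e = self.edges[eid]
                if e.etype != etype:
                    raise MeshError(f"edge type mismatch at {key}")
                if (e.u, e.v) != (v, u):
                    raise MeshError(f"orientation mismatch at {key}")
                self._attach(eid, tid)
            eids.append(eid)
        self.tri_edges[tid] = tuple(eids)
        for v in verts:
            self.vertex_tris[v].add(tid)
        return tid

    @classmethod
    def single_monomer(cls, edge_length=1.0, parity=0, center=(0.0, 0.0, 0.0)):
        """One free equilateral triangle in the z=0 plane."""
        h = edge_length * math.sqrt(3.0) / 2.0
        cx, cy, cz = center
        pts = [
            (cx - 0.5 * edge_length, cy - h / 3.0, cz),
            (cx + 0.5 * edge_length, cy - h / 3.0, cz),
            (cx, cy + 2.0 * h / 3.0, cz),
        ]
        return cls.from_triangles(pts, [((0, 1, 2), parity)])

    # ------------------------------------------------------ monomer exchange
    def insert_monomer(self, eid, apex_pos):
        """Attach a new triangle across free edge ``eid``; returns (tid, vid)."""
        e = self.edges[eid]
        if e.bound:
            raise MeshError("cannot insert on a bound edge")
        t1 = e.tris[0]
        u, v = self.directed(eid, t1)
        parity = 1 - self.tri_parity[t1]
        slot = EDGE_TYPES[parity].index(e.etype)
        x = self._new_vertex(apex_pos)
        # order vertices so the shared slot traverses v -> u
        if slot == 0:
            verts = (v, u, x)
        elif slot == 1:
            verts = (x, v, u)
        else:
            verts = (u, x, v)
        tid = self._tnext
        self._tnext += 1
        self.triangles[tid] = verts
        self.tri_parity[tid] = parity
        self._tri_bound[tid] = 0
        eids = []
        for s, (i, j) in enumerate(SLOT_PAIRS):
            if s == slot:
                self._attach(eid, tid)
                eids.append(eid)
            else:
                eids.append(
                    self._new_edge(verts[i], verts[j], EDGE_TYPES[parity][s], tid)
                )
        self.tri_edges[tid] = tuple(eids)
        for w in verts:
            self.vertex_tris[w].add(tid)
        for w in verts:
            self._dirty_around(w)
        return tid, x

    def removable_monomers(self):
        """Triangles with exactly one bound edge and an exclusive apex vertex."""
        if len(self.triangles) <= 1:
            return []
        out = []
        for tid in self._one_bond_tris:
            eid = self._bound_edge_of(tid)
            apex = self.apex_of(tid, eid)
            if self.vertex_tris[apex] == {tid}:
                out.append(tid)
        return out

    def _bound_edge_of(self, tid):
        for eid in self.tri_edges[tid]:
            if self.edges[eid].bound:
                return eid
        raise MeshError("triangle has no bound edge")

    def remove_monomer(self, tid):
        """Inverse of :meth:`insert_monomer`; returns (eid, apex_pos)."""
        beid = self._bound_edge_of(tid)
        if self._tri_bound[tid] != 1:
            raise MeshError("monomer has more than one bond")
        apex = self.apex_of(tid, beid)
        if self.vertex_tris[apex] != {tid}:
            raise MeshError("apex vertex is shared")
        apex_pos = self.positions[apex]
        self.topo_gen += 1
        for w in self.triangles[tid]:
            self._dirty_around(w)
        self._detach(beid, tid)
        for eid in self.tri_edges[tid]:
            if eid == beid:
                continue
            e = self.edges.pop(eid)
            self.free_edges.discard(eid)
            self.vertex_edges[e.u].discard(eid)
            self.vertex_edges[e.v].discard(eid)
        for w in self.triangles[tid]:
            self.vertex_tris[w].discard(tid)
        del self.positions[apex], self.vertex_tris[apex], self.vertex_edges[apex]
        self.vertex_ids.discard(apex)
        del self.triangles[tid], self.tri_parity[tid], self.tri_edges[tid]
        del self._tri_bound[tid]
        self._one_bond_tris.discard(tid)
        return beid, apex_pos

    # --------------------------------------------------------- fusion/fission
    def fusable(self, eidA, eidB, r_c):
        """Whether two free edges may fuse (type, parity, distance, topology)."""
        if eidA == eidB:
            return False
        eA, eB = self.edges.get(eidA), self.edges.get(eidB)
        if eA is None or eB is None or eA.bound or eB.bound:
            return False
        if eA.etype != eB.etype:
            return False
        tA, tB = eA.tris[0], eB.tris[0]
        if tA == tB or self.tri_parity[tA] == self.tri_parity[tB]:
            return False
        a, b = self.directed(eidA)
        c, d = self.directed(eidB)
        if a == c or b == d:  # would collapse an edge to a point
            return False
        # a == d and b == c is allowed: closing the last bond of a zipped
        # crack merges no vertices; the reverse (interior fission) is outside
        # the move set, making the final heal irreversible.
        # merging a~d or b~c must not create degenerate triangles or self-loops
        for p, q in ((a, d), (b, c)):
            if p == q:
                continue
            if self.vertex_tris[p] & self.vertex_tris[q]:
                return False
            for ee in self.vertex_edges[p]:
                edge = self.edges[ee]
                if edge.u == q or edge.v == q:
                    return False
        pa, pb = self.positions[a], self.positions[b]
        pc, pd = self.positions[c], self.positions[d]
        r2 = r_c * r_c
        if _d2(pa, pd) > r2 or _d2(pb, pc) > r2:
            return False
        return True

    def fusion_candidates(self, r_c):
        """All unordered fusable free-edge pairs within capture distance."""
        free = list(self.free_edges)
        pos = self.positions
        mids = []
        for eid in free:
            e = self.edges[eid]
            pu, pv = pos[e.u], pos[e.v]
            mids.append(
                (
                    0.5 * (pu[0] + pv[0]),
                    0.5 * (pu[1] + pv[1]),
                    0.5 * (pu[2] + pv[2]),
                )
            )
        # both vertex pairs within r_c implies midpoints within r_c
        r2 = (1.0000001 * r_c) ** 2
        out = []
        for i in range(len(free)):
            mi = mids[i]
            for j in range(i + 1, len(free)):
                mj = mids[j]
                dx = mi[0] - mj[0]
                dy = mi[1] - mj[1]
                dz = mi[2] - mj[2]
                if dx * dx + dy * dy + dz * dz > r2:
                    continue
                if self.fusable(free[i], free[j], r_c):
                    out.append((free[i], free[j]))
        return out

    def fuse(self, eidA, eidB):
        """Bind free edges A and B, merging their vertex pairs (midpoints).

        Returns (eidA, n_merged).  ``eidA`` survives as the bound edge; its
        first triangle keeps ownership of the direction.
        """
        eA, eB = self.edges[eidA], self.edges[eidB]
        tB = eB.tris[0]
        a, b = self.directed(eidA)
        c, d = self.directed(eidB)
        for w in (a, b, c, d):
            self._dirty_around(w)
        merged = 0
        if a != d:
            self._merge_vertices(a, d)
            merged += 1
        if b != c:
            self._merge_vertices(b, c)
            merged += 1
        # retarget tB's slot from eidB to eidA
        slot = self.tri_edges[tB].index(eidB)
        te = list(self.tri_edges[tB])
        te[slot] = eidA
        self.tri_edges[tB] = tuple(te)
        self.free_edges.discard(eidB)
        self.vertex_edges[eB.u].discard(eidB)
        self.vertex_edges[eB.v].discard(eidB)
        del self.edges[eidB]
        self._attach(eidA, tB)
        self._dirty_around(a)
        self._dirty_around(b)
        return eidA, merged

    def _merge_vertices(self, keep, gone):
        """Relabel ``gone`` as ``keep``; ``keep`` moves to the midpoint."""
        self.topo_gen += 1
        pk, pg = self.positions[keep], self.positions[gone]
        self.positions[keep] = (
            0.5 * (pk[0] + pg[0]),
            0.5 * (pk[1] + pg[1]),
            0.5 * (pk[2] + pg[2]),
        )
        for tid in list(self.vertex_tris[gone]):
            self.triangles[tid] = tuple(
                keep if w == gone else w for w in self.triangles[tid]
            )
            self.vertex_tris[keep].add(tid)
        for eid in list(self.vertex_edges[gone]):
            e = self.edges[eid]
            if e.u == gone:
                e.u = keep
            if e.v == gone:
                e.v = keep
            self.vertex_edges[keep].add(eid)
        del self.positions[gone], self.vertex_tris[gone], self.vertex_edges[gone]
        self.vertex_ids.discard(gone)

    def fission_candidates(self):
        """Bound edges adjacent to a boundary vertex (fissionable).

        Interior edges of a closed tube are locked; restricting fission to
        the boundary keeps the move local and exactly mirrors the fusion
        move, whose vertex merges always leave a boundary-adjacent bond.
        """
        out = []
        seen = set()
        for feid in self.free_edges:
            fe = self.edges[feid]
            for p in (fe.u, fe.v):
                for eid in self.vertex_edges[p]:
                    if eid not in seen:
                        seen.add(eid)
                        if self.edges[eid].bound:
                            out.append(eid)
        return out

    def fission_disconnects(self, eid):
        """Would unbinding ``eid`` split the sheet into two components?"""
        e = self.edges[eid]
        t1, t2 = e.tris
        seen = {t1}
        queue = deque([t1])
        while queue:
            t = queue.popleft()
            for ee in self.tri_edges[t]:
                if ee == eid:
                    continue
                edge = self.edges[ee]
                if not edge.bound:
                    continue
                for tn in edge.tris:
                    if tn == t2:
                        return False
                    if tn not in seen:
                        seen.add(tn)
                        queue.append(tn)
        return True

    def _fan(self, p, t_start, e_block):
        """Triangles around vertex ``p`` reachable from ``t_start`` across
        bound edges, never crossing ``e_block``; stops at free edges."""
        fan = [t_start]
        t, e_prev = t_start, e_block
        while True:
            nxt = None
            for eid in self.tri_edges[t]:
                if eid == e_prev:
                    continue
                e = self.edges[eid]
                if e.u == p or e.v == p:
                    nxt = eid
                    break
            if nxt is None:
                raise MeshError("vertex fan walk failed")
            e = self.edges[nxt]
            if not e.bound or nxt == e_block:
                return fan
            t = e.tris[0] if e.tris[0] != t else e.tris[1]
            e_prev = nxt
            fan.append(t)

    def fission(self, eid, displacements=None, rng=None, r_c=0.0):
        """Unbind edge ``eid`` (exact inverse of :meth:`fuse`).

        Endpoints whose triangle fans separate are split into two vertices,
        displaced by +-d/2 along a vector ``d`` drawn uniformly from a ball of
        radius ``r_c`` (or taken from ``displacements`` when rolling back a
        rejected fusion).  Returns (new_free_eid, splits) with ``splits`` a
        list of (kept_vid, new_vid, d) tuples.
        """
        e = self.edges[eid]
        t1, t2 = e.tris
        u, v = e.u, e.v
        self.topo_gen += 1
        self._dirty_around(u)
        self._dirty_around(v)
        plan = []  # (old_vid, fan) for endpoints to split
        for p in (u, v):
            fan = self._fan(p, t2, eid)
            if t1 not in fan:
                plan.append((p, fan))
        # detach t2 from e, giving it a fresh free edge
        self._detach(eid, t2)
        slot = self.tri_edges[t2].index(eid)
        etype = self.edges[eid].etype
        i, j = SLOT_PAIRS[slot]
        u2, v2 = self.triangles[t2][i], self.triangles[t2][j]
        eid2 = self._new_edge(u2, v2, etype, t2)
        te = list(self.tri_edges[t2])
        te[slot] = eid2
        self.tri_edges[t2] = tuple(te)
        # split vertices
        splits = []
        for p, fan in plan:
            x = self.positions[p]
            if displacements is not None:
                dx, dy, dz = displacements[len(splits)]
            else:
                dx, dy, dz = rng.in_ball(r_c)
            p2 = self._new_vertex((x[0] - 0.5 * dx, x[1] - 0.5 * dy, x[2] - 0.5 * dz))
            self.positions[p] = (x[0] + 0.5 * dx, x[1] + 0.5 * dy, x[2] + 0.5 * dz)
            relabeled = set()
            for t in fan:
                self.triangles[t] = tuple(p2 if w == p else w for w in self.triangles[t])
                self.vertex_tris[p].discard(t)
                self.vertex_tris[p2].add(t)
                for ee in self.tri_edges[t]:
                    if ee in relabeled:
                        continue
                    edge = self.edges[ee]
                    if edge.u == p and all(tt in fan for tt in edge.tris):
                        edge.u = p2
                    elif edge.v == p and all(tt in fan for tt in edge.tris):
                        edge.v = p2
                    else:
                        continue
                    relabeled.add(ee)
                    self.vertex_edges[p].discard(ee)
                    self.vertex_edges[p2].add(ee)
            splits.append((p, p2, (dx, dy, dz)))
        for p, p2, _ in splits:
            self._dirty_around(p)
            self._dirty_around(p2)
        self._dirty_around(u)
        self._dirty_around(v)
        return eid2, splits

    # ------------------------------------------------------------- topology
    def boundary_cycle_count(self):
        """Number of connected components of the free-edge graph."""
        parent = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for eid in self.free_edges:
            e = self.edges[eid]
            for w in (e.u, e.v):
                if w not in parent:
                    parent[w] = w
            ru, rv = find(e.u), find(e.v)
            if ru != rv:
                parent[ru] = rv
        return len({find(x) for x in parent})

    def boundary_vertices(self):
        out = set()
        for eid in self.free_edges:
            e = self.edges[eid]
            out.add(e.u)
            out.add(e.v)
        return out

    def euler_characteristic(self):
        return self.n_vertices - len(self.edges) + self.n_triangles

    # ------------------------------------------------------------ validation
    def check_invariants(self):
        """Raise MeshError on any structural inconsistency (test helper)."""
        for tid, eids in self.tri_edges.items():
            types = sorted(self.edges[e].etype for e in eids)
            if types != [1, 2, 3]:
                raise MeshError(f"triangle {tid} lacks one edge of each type")
            parity = self.tri_parity[tid]
            for slot, eid in enumerate(eids):
                e = self.edges[eid]
                if e.etype != EDGE_TYPES[parity][slot]:
                    raise MeshError(f"slot type mismatch in triangle {tid}")
                i, j = SLOT_PAIRS[slot]
                a, b = self.triangles[tid][i], self.triangles[tid][j]
                if {a, b} != {e.u, e.v}:
                    raise MeshError(f"edge endpoints mismatch in triangle {tid}")
                if tid not in e.tris:
                    raise MeshError(f"edge {eid} missing triangle {tid}")
        for eid, e in self.edges.items():
            if len(e.tris) not in (1, 2):
                raise MeshError(f"edge {eid} has {len(e.tris)} triangles")
            if e.bound != (eid in self.bound_edges) or (not e.bound) != (
                eid in self.free_edges
            ):
                raise MeshError(f"edge {eid} state bookkeeping broken")
            if e.bound:
                p0, p1 = (self.tri_parity[t] for t in e.tris)
                if p0 == p1:
                    raise MeshError(f"bound edge {eid} joins equal parities")
                a, b = self.directed(eid, e.tris[0])
                c, d = self.directed(eid, e.tris[1])
                if (a, b) != (d, c):
                    raise MeshError(f"bound edge {eid} orientation inconsistent")
        for tid, nb in self._tri_bound.items():
            real = sum(1 for e in self.tri_edges[tid] if self.edges[e].bound)
            if real != nb:
                raise MeshError(f"bound count stale for triangle {tid}")
        # single connected component
        if self.triangles:
            seen = set()
            start = next(iter(self.triangles))
            queue = deque([start])
            seen.add(start)
            while queue:
                t = queue.popleft()
                for eid in self.tri_edges[t]:
                    for tn in self.edges[eid].tris:
                        if tn not in seen:
                            seen.add(tn)
                            queue.append(tn)
            if len(seen) != self.n_triangles:
                raise MeshError("sheet is not a single connected component")


def _d2(p, q):
    dx = p[0] - q[0]
    dy = p[1] - q[1]
    dz = p[2] - q[2]
    return dx * dx + dy * dy + dz * dz
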