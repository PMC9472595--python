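"""Grand-canonical kinetic Monte Carlo engine for tubule self-assembly.

A single structure exchanges monomers with an ideal bath at fixed chemical
potential ``mu`` (activity ``exp(mu)`` per ``l0**3``; the standard-state
concentration corresponds to one monomer per ``l0**3``).  The move set is

* **vertex moves** — uniform displacement in a cube, Metropolis on the
  Hamiltonian; one attempted vertex move per vertex defines one sweep;
* **association / dissociation** — a monomer is grown across a uniformly
  chosen free boundary edge, its apex proposed uniformly in a cube around
  the preferred-dihedral position; only monomers with exactly one bond and an
  exclusive apex can dissociate, so a single connected structure is
  maintained;
* **edge fusion / fission** — two nearby free edges of equal type bind
  (vertex pairs merged at their midpoints), or a bound edge splits (the lost
  separation vectors drawn uniformly from a ball of radius ``r_c``); this is
  an exact reversible-jump pair.

Move types are attempted with state-dependent weights (vertex: one per
vertex, exchange: ``p_exchange`` per free edge, fusion/fission: ``f_fusion``
per vertex) and every acceptance ratio carries the full forward/reverse
selection-probability correction, so the chain satisfies detailed balance
with respect to the grand-canonical Boltzmann distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .analysis import DefectiveStructureError, lattice_holonomies
from .energetics import (
    EnergyParams,
    NeighborhoodCache,
    deletion_delta,
    insertion_delta,
    region_energy,
)
from .lattice import SQRT3, TubuleIndices, circumference
from .mesh import TriangulatedSheet
from .util import RandomPool


@dataclass(frozen=True)
class BathConditions:
    """Monomer bath state; ``c0 = c_SS * exp(mu / kT)``."""

    mu: float = -3.0
    c_SS: float = 10e-6  # molar; one monomer per l0^3 in simulation units
    T: float = 1.0

    def __post_init__(self):
        if self.c_SS <= 0 or self.T <= 0:
            raise ValueError("c_SS and T must be positive")

    @property
    def c0(self) -> float:
        return self.c_SS * math.exp(self.mu / self.T)


@dataclass(frozen=True)
class SimulationConfig:
    """Kinetic and bookkeeping parameters of one assembly run.

    ``f_fusion`` is the attempt-frequency ratio of fusion/fission moves to
    vertex moves (the unit timescale); ``p_exchange`` plays the same role for
    association/dissociation per free boundary edge.  The run stops when the
    tubule length reaches ``stop_length_factor`` times the target
    circumference (measured as N*a0 / (pi*D0)), or at ``max_sweeps``.
    """

    f_fusion: float = 1e-3
    p_exchange: float = 0.02
    delta_v: float = 0.1
    h_insert: float = 0.25  # association proposal-cube half-width (l0)
    r_c: float = 0.35  # fusion capture / fission displacement radius (l0)
    seed: int = 1
    stop_length_factor: float = 3.0
    max_sweeps: float = 1e5
    record_every: float = 20.0
    log_events: bool = True

    def __post_init__(self):
        if min(self.f_fusion, self.p_exchange, self.delta_v) < 0 or self.r_c <= 0:
            raise ValueError("frequencies must be >= 0 and r_c > 0")

    @property
    def v_p(self) -> float:
        return (2.0 * self.h_insert) ** 3

    @property
    def v_d(self) -> float:
        return 4.0 / 3.0 * math.pi * self.r_c**3


@dataclass
class TrajectoryRecord:
    """Time series and event log of one assembly trajectory."""

    seed: int
    target: TubuleIndices
    series: list = field(default_factory=list)  # (tau, N, bound, cycles)
    events: list = field(default_factory=list)  # (tau, kind)
    closed: bool = False
    N_close: int | None = None
    tau_close: float | None = None
    finished: bool = False
    tau_end: float = 0.0
    n_attempts: int = 0
    sheet: TriangulatedSheet | None = None


def _ideal_apex(sheet, eid, theta0, l0, tid=None):
    """Apex position forming an equilateral triangle across edge ``eid`` (as
    seen from triangle ``tid``) at exactly the preferred dihedral angle of
    its edge type."""
    e = sheet.edges[eid]
    t1 = e.tris[0] if tid is None else tid
    u, v = sheet.directed(eid, t1)
    w1 = sheet.apex_of(t1, eid)
    pos = sheet.positions
    pu, pv, pw = pos[u], pos[v], pos[w1]
    ex, ey, ez = pv[0] - pu[0], pv[1] - pu[1], pv[2] - pu[2]
    el = math.sqrt(ex * ex + ey * ey + ez * ez)
    ex, ey, ez = ex / el, ey / el, ez / el
    ax, ay, az = pw[0] - pu[0], pw[1] - pu[1], pw[2] - pu[2]
    nx, ny, nz = ey * az - ez * ay, ez * ax - ex * az, ex * ay - ey * ax
    nl = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nl, ny / nl, nz / nl
    # in-plane direction perpendicular to the edge, away from w1
    qx, qy, qz = ny * ez - nz * ey, nz * ex - nx * ez, nx * ey - ny * ex
    mx, my, mz = 0.5 * (pu[0] + pv[0]), 0.5 * (pu[1] + pv[1]), 0.5 * (pu[2] + pv[2])
    if (mx - pw[0]) * qx + (my - pw[1]) * qy + (mz - pw[2]) * qz < 0:
        qx, qy, qz = -qx, -qy, -qz
    chi = theta0[e.etype] - math.pi
    h = SQRT3 / 2.0 * l0
    cx, sx = h * math.cos(chi), h * math.sin(chi)
    return (
        mx + cx * qx + sx * nx,
        my + cx * qy + sx * ny,
        mz + cx * qz + sx * nz,
    )


class AssemblySimulator:
    """One grand-canonical assembly trajectory from a single monomer."""

    def __init__(
        self,
        target: TubuleIndices,
        p: EnergyParams,
        bath: BathConditions = BathConditions(),
        cfg: SimulationConfig = SimulationConfig(),
        sheet: TriangulatedSheet | None = None,
    ):
        self.target = TubuleIndices(*target)
        self.p = p
        self.bath = bath
        self.cfg = cfg
        self.sheet = sheet if sheet is not None else TriangulatedSheet.single_monomer(p.l0)
        self.rng = RandomPool(cfg.seed)
        self.tau = 0.0
        self.record = TrajectoryRecord(seed=cfg.seed, target=self.target)
        self.record.sheet = self.sheet
        self._beta = 1.0 / bath.T
        self._nbcache = NeighborhoodCache(self.sheet, p)

    # ------------------------------------------------------------- plumbing
    def _weight(self):
        s = self.sheet
        return (
            s.n_vertices * (1.0 + self.cfg.f_fusion)
            + self.cfg.p_exchange * s.n_free_edges
        )

    def _log(self, kind):
        if self.cfg.log_events:
            self.record.events.append((self.tau, kind))

    def _metropolis(self, ratio):
        return ratio >= 1.0 or self.rng.u() < ratio

    # ----------------------------------------------------------- move: vertex
    def vertex_move(self) -> bool:
        """Displace one uniformly chosen vertex uniformly in a cube."""
        s = self.sheet
        vid = s.vertex_ids.pick(self.rng.u())
        dv = self.cfg.delta_v
        if dv == 0.0:
            return True
        dx, dy, dz = self.rng.in_cube(dv)
        old = s.positions[vid]
        new = (old[0] + dx, old[1] + dy, old[2] + dz)
        dE = self._nbcache.delta(vid, new)
        if dE <= 0.0 or self.rng.u() < math.exp(-self._beta * dE):
            s.positions[vid] = new
            return True
        return False

    # ------------------------------------------------------ move: association
    def attempt_association(self) -> bool:
        s, cfg, rng = self.sheet, self.cfg, self.rng
        F_i = s.n_free_edges
        if F_i == 0:
            return False
        W_i = self._weight()
        eid = s.free_edges.pick(rng.u())
        ideal = _ideal_apex(s, eid, self.p.theta0, self.p.l0)
        dx, dy, dz = rng.in_cube(cfg.h_insert)
        apex = (ideal[0] + dx, ideal[1] + dy, ideal[2] + dz)
        dE = insertion_delta(s, eid, apex, self.p)
        # post-insertion counts are predictable: the new monomer is removable,
        # the edge's owner triangle (one more bond) may stop being so
        removable = s.removable_monomers()
        owner = s.edges[eid].tris[0]
        if s.n_triangles == 1:
            R_j = 2  # both monomers of the new dimer can dissociate
        else:
            R_j = len(removable) + 1 - (1 if owner in removable else 0)
        F_j = F_i + 1
        V = s.n_vertices
        W_j = (V + 1) * (1.0 + cfg.f_fusion) + cfg.p_exchange * F_j
        ratio = (
            math.exp(self._beta * (self.bath.mu - dE))
            * cfg.v_p
            * F_j
            * W_i
            / (W_j * R_j)
        )
        if self._metropolis(ratio):
            s.insert_monomer(eid, apex)
            self._log("insert")
            return True
        return False

    # ----------------------------------------------------- move: dissociation
    def attempt_dissociation(self) -> bool:
        s, cfg, rng = self.sheet, self.cfg, self.rng
        removable = s.removable_monomers()
        R_i = len(removable)
        if R_i == 0:
            return False
        tid = removable[rng.index(R_i)]
        beid = s._bound_edge_of(tid)
        apex = s.apex_of(tid, beid)
        e = s.edges[beid]
        tother = e.tris[0] if e.tris[0] != tid else e.tris[1]
        # reverse insertion must be able to re-propose this apex position
        ideal = _ideal_apex(s, beid, self.p.theta0, self.p.l0, tid=tother)
        pa = s.positions[apex]
        h = cfg.h_insert
        if (
            abs(pa[0] - ideal[0]) > h
            or abs(pa[1] - ideal[1]) > h
            or abs(pa[2] - ideal[2]) > h
        ):
            return False
        dE = deletion_delta(s, tid, self.p)
        W_i = self._weight()
        F_i = s.n_free_edges
        V = s.n_vertices
        W_j = (V - 1) * (1.0 + cfg.f_fusion) + cfg.p_exchange * (F_i - 1)
        ratio = (
            math.exp(self._beta * (-self.bath.mu - dE))
            * R_i
            * W_i
            / (cfg.v_p * F_i * W_j)
        )
        if self._metropolis(ratio):
            s.remove_monomer(tid)
            self._log("delete")
            return True
        return False

    # --------------------------------------------------------- move: fusion
    def attempt_fusion(self) -> bool:
        s, cfg, rng = self.sheet, self.cfg, self.rng
        cands = s.fusion_candidates(cfg.r_c)
        Phi_i = len(cands)
        if Phi_i == 0:
            return False
        eA, eB = cands[rng.index(Phi_i)]
        a, b = s.directed(eA)
        c, d = s.directed(eB)
        pos = s.positions
        disp = []
        for pq in ((a, d), (b, c)):
            if pq[0] != pq[1]:
                pp, qq = pos[pq[0]], pos[pq[1]]
                disp.append((pp[0] - qq[0], pp[1] - qq[1], pp[2] - qq[2]))
        V_i, W_i = s.n_vertices, self._weight()
        E_before = region_energy(s, {a, b, c, d}, self.p)
        fused_eid, k = s.fuse(eA, eB)
        E_after = region_energy(s, {a, b}, self.p)
        dE = E_after - E_before
        V_j, W_j = s.n_vertices, self._weight()
        Psi_j = len(s.fission_candidates())
        ratio = (
            math.exp(-self._beta * dE)
            * V_j
            * W_i
            * Phi_i
            / (V_i * W_j * Psi_j * cfg.v_d**k)
        )
        if self._metropolis(ratio):
            self._log("fuse")
            if not self.record.closed:
                self._check_closure()
            return True
        s.fission(fused_eid, displacements=disp)
        return False

    # --------------------------------------------------------- move: fission
    def attempt_fission(self) -> bool:
        s, cfg, rng = self.sheet, self.cfg, self.rng
        fissionable = s.fission_candidates()
        Psi_i = len(fissionable)
        if Psi_i == 0:
            return False
        eid = fissionable[rng.index(Psi_i)]
        if s.fission_disconnects(eid):
            return False
        e = s.edges[eid]
        u, v = e.u, e.v
        V_i, W_i = s.n_vertices, self._weight()
        E_before = region_energy(s, {u, v}, self.p)
        eid2, splits = s.fission(eid, rng=rng, r_c=cfg.r_c)
        k = len(splits)
        if k == 0:
            # would create a zero-width slit with no reverse fusion move
            s.fuse(eid, eid2)
            return False
        region_after = {u, v} | {p2 for _, p2, _ in splits}
        E_after = region_energy(s, region_after, self.p)
        dE = E_after - E_before
        V_j, W_j = s.n_vertices, self._weight()
        Phi_j = len(s.fusion_candidates(cfg.r_c))
        ratio = (
            math.exp(-self._beta * dE)
            * V_j
            * W_i
            * Psi_i
            * cfg.v_d**k
            / (V_i * W_j * Phi_j)
        )
        if self._metropolis(ratio):
            self._log("fission")
            return True
        s.fuse(eid, eid2)
        return False

    def attempt_fusion_fission(self) -> bool:
        """Randomly attempt either an edge fusion or an edge fission."""
        if self.rng.u() < 0.5:
            return self.attempt_fusion()
        return self.attempt_fission()

    # ------------------------------------------------------------- trajectory
    def _check_closure(self):
        try:
            hol = lattice_holonomies(self.sheet)
            closed = bool(hol)
        except DefectiveStructureError:
            closed = True
        if closed:
            self.record.closed = True
            self.record.N_close = self.sheet.n_triangles
            self.record.tau_close = self.tau
            self._log("closure")

    def step(self) -> str:
        """One elementary attempt; returns the move kind attempted."""
        s, cfg = self.sheet, self.cfg
        V = s.n_vertices
        w_v = V
        w_x = cfg.p_exchange * s.n_free_edges
        w_f = cfg.f_fusion * V
        W = w_v + w_x + w_f
        self.tau += 1.0 / W
        self.record.n_attempts += 1
        u = self.rng.u() * W
        if u < w_v:
            self.vertex_move()
            return "vertex"
        if u < w_v + w_x:
            if self.rng.u() < 0.5:
                self.attempt_association()
            else:
                self.attempt_dissociation()
            return "exchange"
        self.attempt_fusion_fission()
        return "fusion_fission"

    def stop_size(self) -> int:
        """Monomer count at which L reaches stop_length_factor * |C_target|."""
        C = circumference(self.target)
        a0 = SQRT3 / 4.0 * self.p.l0**2
        return math.ceil(self.cfg.stop_length_factor * C * C / a0)

    def run(self) -> TrajectoryRecord:
        cfg = self.cfg
        rec = self.record
        N_stop = self.stop_size()
        next_rec = 0.0
        while True:
            if self.tau >= next_rec:
                rec.series.append(
                    (
                        self.tau,
                        self.sheet.n_triangles,
                        self.sheet.n_bound_edges,
                        self.sheet.boundary_cycle_count(),
                    )
                )
                next_rec += cfg.record_every
            if self.sheet.n_triangles >= N_stop:
                rec.finished = True
                break
            if self.tau >= cfg.max_sweeps:
                rec.finished = False
                break
            self.step()
        rec.tau_end = self.tau
        return rec


def run_trajectory(
    target: TubuleIndices,
    p: EnergyParams,
    bath: BathConditions = BathConditions(),
    cfg: SimulationConfig = SimulationConfig(),
) -> TrajectoryRecord:
    """Run one assembly trajectory from a single monomer to the stop rule."""
    return AssemblySimulator(target, p, bath, cfg).run()
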