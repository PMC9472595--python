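"""Classify assembled structures and aggregate geometry distributions.

A finished structure is *defect-free* when it is a closed tubule (exactly two
boundary cycles) whose intrinsic lattice coordinates are globally consistent
with a single rollup vector; *defective* when it closed but carries residual
cracks (extra boundary cycles) or inconsistent local lattice geometry; and
*open* when it never closed (the spiral "toilet paper roll" outcome).

The rollup indices of a closed tubule are measured purely topologically: each
directed triangle edge advances intrinsic lattice coordinates by a fixed step
determined by the triangle's sublattice parity, and the holonomy of the
resulting coordinate field around the tubule waist is the rollup vector.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

from .lattice import (
    LatticeConstants,
    TubuleIndices,
    circumference,
)
from .mesh import LATTICE_STEPS, SLOT_PAIRS, NotClosedError, TriangulatedSheet

DEFECT_FREE = "defect_free"
DEFECTIVE = "defective"
OPEN = "open"
UNFINISHED = "unfinished"


class DefectiveStructureError(ValueError):
    """Lattice coordinates are inconsistent with a single tubule geometry."""


def lattice_holonomies(sheet: TriangulatedSheet):
    """Intrinsic-coordinate BFS; returns the set of nonzero loop holonomies.

    Raises DefectiveStructureError when the coordinate field is inconsistent
    (holonomies that are not collinear integer multiples of one generator).
    """
    adj = {}
    for tid, tri in sheet.triangles.items():
        parity = sheet.tri_parity[tid]
        for slot, (i, j) in enumerate(SLOT_PAIRS):
            u, v = tri[i], tri[j]
            si, sj = LATTICE_STEPS[parity][slot]
            adj.setdefault(u, []).append((v, si, sj))
            adj.setdefault(v, []).append((u, -si, -sj))
    if not adj:
        return set()
    coords = {}
    root = next(iter(adj))
    coords[root] = (0, 0)
    queue = deque([root])
    hol = set()
    while queue:
        u = queue.popleft()
        cu = coords[u]
        for v, si, sj in adj[u]:
            cv = (cu[0] + si, cu[1] + sj)
            if v not in coords:
                coords[v] = cv
                queue.append(v)
            else:
                h = (cv[0] - coords[v][0], cv[1] - coords[v][1])
                if h != (0, 0):
                    if h[0] < 0 or (h[0] == 0 and h[1] < 0):
                        h = (-h[0], -h[1])
                    hol.add(h)
    if not hol:
        return set()
    g = min(hol, key=lambda h: h[0] * h[0] + h[0] * h[1] + h[1] * h[1])
    for h in hol:
        if h[0] * g[1] != h[1] * g[0]:
            raise DefectiveStructureError(
                f"non-collinear loop holonomies {g} and {h}"
            )
        k = (h[0] // g[0]) if g[0] else (h[1] // g[1])
        if (k * g[0], k * g[1]) != h:
            raise DefectiveStructureError(
                f"holonomy {h} is not an integer multiple of {g}"
            )
    return hol


def _canonical_rollup(g):
    """Canonical (m, n, handedness) from a raw holonomy vector."""
    p, q = g
    orbit = []
    a, b = p, q
    for _ in range(6):
        a, b = -b, a + b
        orbit.append((a, b))
    nonneg = [(a, b) for a, b in orbit if a >= 1 and b >= 0]
    if not nonneg:
        raise DefectiveStructureError(f"degenerate rollup vector {g}")
    a, b = max(nonneg)
    if b > a:
        return TubuleIndices(b, a), -1
    return TubuleIndices(a, b), +1


def classify_geometry_full(sheet: TriangulatedSheet):
    """(TubuleIndices, handedness) of a closed tubule."""
    hol = lattice_holonomies(sheet)
    if not hol:
        raise NotClosedError("no closed waist loop: structure is not a tubule")
    g = min(hol, key=lambda h: h[0] * h[0] + h[0] * h[1] + h[1] * h[1])
    return _canonical_rollup(g)


def classify_geometry(sheet: TriangulatedSheet) -> TubuleIndices:
    """Rollup indices (m, n) of a closed tubule (carbon-nanotube convention)."""
    return classify_geometry_full(sheet)[0]


# --------------------------------------------------------------------------
# outcome records
# --------------------------------------------------------------------------

@dataclass
class OutcomeRecord:
    """Final classification of one assembly trajectory."""

    category: str
    mn: TubuleIndices | None = None
    handedness: int = 0
    N_final: int = 0
    N_close: int | None = None
    L: float | None = None
    D: float | None = None
    L_close: float | None = None
    seed: int | None = None


def measure_L_D(mn: TubuleIndices, N: int, lat: LatticeConstants = LatticeConstants()):
    """Length and diameter of an N-monomer (m, n) tubule: D = |C|/pi,
    L = N*a0/(pi*D)."""
    D = circumference(mn, lat) / math.pi
    L = N * lat.a0 / (math.pi * D)
    return L, D


def classify_outcome(traj, lat: LatticeConstants = LatticeConstants()) -> OutcomeRecord:
    """Classify a finished trajectory as defect-free / defective / open."""
    sheet = traj.sheet
    N = sheet.n_triangles
    if not traj.finished:
        return OutcomeRecord(category=UNFINISHED, N_final=N, seed=traj.seed)
    if not traj.closed:
        return OutcomeRecord(category=OPEN, N_final=N, seed=traj.seed)
    cycles = sheet.boundary_cycle_count()
    if cycles != 2:
        return OutcomeRecord(
            category=DEFECTIVE, N_final=N, N_close=traj.N_close, seed=traj.seed
        )
    try:
        mn, hand = classify_geometry_full(sheet)
    except (DefectiveStructureError, NotClosedError):
        return OutcomeRecord(
            category=DEFECTIVE, N_final=N, N_close=traj.N_close, seed=traj.seed
        )
    L, D = measure_L_D(mn, N, lat)
    L_close = None
    if traj.N_close is not None:
        L_close, _ = measure_L_D(mn, traj.N_close, lat)
    return OutcomeRecord(
        category=DEFECT_FREE,
        mn=mn,
        handedness=hand,
        N_final=N,
        N_close=traj.N_close,
        L=L,
        D=D,
        L_close=L_close,
        seed=traj.seed,
    )


@dataclass
class DistributionSummary:
    """Ensemble summary of assembly outcomes."""

    n_trials: int
    frac_defect_free: float
    frac_defective: float
    frac_open: float
    geometry_fractions: dict  # (m, n) -> fraction within defect-free set
    target: TubuleIndices | None
    target_yield: float  # defect-free target fraction of the whole population
    mean_D: float | None
    delta_D: float | None
    mean_L_close: float | None

    def to_dict(self):
        return {
            "n_trials": self.n_trials,
            "frac_defect_free": self.frac_defect_free,
            "frac_defective": self.frac_defective,
            "frac_open": self.frac_open,
            "geometry_fractions": {
                f"{m},{n}": f for (m, n), f in self.geometry_fractions.items()
            },
            "target": (f"{self.target.m},{self.target.n}" if self.target else None),
            "target_yield": self.target_yield,
            "mean_D": self.mean_D,
            "delta_D": self.delta_D,
            "mean_L_close": self.mean_L_close,
        }


def aggregate(records, target: TubuleIndices | None = None) -> DistributionSummary:
    """Aggregate finished outcome records into a distribution summary.

    ``delta_D`` is the population standard deviation of the diameter over the
    defect-free records only.
    """
    recs = [r for r in records if r.category != UNFINISHED]
    if not recs:
        raise ValueError("no finished records to aggregate")
    n = len(recs)
    free = [r for r in recs if r.category == DEFECT_FREE]
    n_free = len(free)
    counts = {}
    for r in free:
        key = (r.mn.m, r.mn.n)
        counts[key] = counts.get(key, 0) + 1
    geo = {k: c / n_free for k, c in counts.items()} if n_free else {}
    if target is not None:
        target = TubuleIndices(*target)
        tkey = (target.m, target.n)
        tyield = counts.get(tkey, 0) / n
    else:
        tyield = 0.0
    if n_free:
        ds = [r.D for r in free]
        mean_D = sum(ds) / n_free
        delta_D = math.sqrt(sum((d - mean_D) ** 2 for d in ds) / n_free)
        lcs = [r.L_close for r in free if r.L_close is not None]
        mean_Lc = sum(lcs) / len(lcs) if lcs else None
    else:
        mean_D = delta_D = mean_Lc = None
    return DistributionSummary(
        n_trials=n,
        frac_defect_free=n_free / n,
        frac_defective=sum(1 for r in recs if r.category == DEFECTIVE) / n,
        frac_open=sum(1 for r in recs if r.category == OPEN) / n,
        geometry_fractions=geo,
        target=target,
        target_yield=tyield,
        mean_D=mean_D,
        delta_D=delta_D,
        mean_L_close=mean_Lc,
    )
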