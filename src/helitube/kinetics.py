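"""Deterministic growth-closure kinetic model of tubule polymorphism.

Before closure the assembling structure is idealised as a circular disk bent
to the target curvature.  It grows by one monomer at regular intervals
``dt_N = 1/k_grow(N)`` with ``k_grow`` proportional to the disk perimeter,
and while at size N it attempts to close into any geometry (m, n) that the
disk width can span, at a rate suppressed by the bending free-energy barrier
of deforming the whole disk to that geometry's curvature:

    k_close^(m,n)(N) = k0_close * I^(m,n)(N) * exp(-dG^(m,n)(N)),
    dG^(m,n)(N)      = N * a0 * (B~/2) (2/D_mn - 2/D0)^2.

Closure is irreversible; summing the per-size closure probabilities gives
the distribution of assembled geometries and the mass that never closes
(open structures).  The deterministic recursion is validated by a
continuous-time Gillespie simulation of the same competing rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .equilibrium import (
    bending_energy_per_monomer,
    candidate_geometries,
    discrete_to_continuum_modulus,
)
from .lattice import LatticeConstants, TubuleIndices, diameter


@dataclass(frozen=True)
class KineticParams:
    """Rates and sizes of the growth-closure competition."""

    target: TubuleIndices
    B: float = 20.0
    k0_grow: float = 1.0
    k0_close: float = 1.0
    N0: int = 1
    N_max: int = 600
    lat: LatticeConstants = LatticeConstants()

    def __post_init__(self):
        if self.k0_grow < 0 or self.k0_close < 0:
            raise ValueError("rates must be >= 0")
        if not self.N0 < self.N_max:
            raise ValueError("require N0 < N_max")

    @property
    def B_tilde(self) -> float:
        return discrete_to_continuum_modulus(self.B)


def disk_perimeter(N: int, lat: LatticeConstants = LatticeConstants()) -> float:
    """Isoperimetric perimeter of an N-monomer circular disk,
    P(N) = 2*sqrt(pi*N*a0)."""
    return 2.0 * math.sqrt(math.pi * N * lat.a0)


def growth_rate(N: int, kp: KineticParams) -> float:
    """k_grow(N) = k0_grow * P(N) / l0 (proportional to boundary length)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return kp.k0_grow * disk_perimeter(N, kp.lat) / kp.lat.l0


def disk_width(N: int, lat: LatticeConstants = LatticeConstants()) -> float:
    """Diameter 2*sqrt(N*a0/pi) of the isoperimetric disk."""
    return 2.0 * math.sqrt(N * lat.a0 / math.pi)


def closure_indicator(mn: TubuleIndices, N: int, kp: KineticParams) -> int:
    """1 when the disk is wide enough to span the (m, n) circumference,
    2*sqrt(N*a0/pi) >= pi*D_mn; monotone nondecreasing in N."""
    D = diameter(TubuleIndices(*mn), kp.lat)
    return 1 if disk_width(N, kp.lat) >= math.pi * D else 0


def closure_barrier(mn: TubuleIndices, N: int, kp: KineticParams) -> float:
    """dG^(m,n)(N): whole-disk bending cost of adopting the (m, n) geometry.

    Uses the discrete per-monomer bending energy
    ``sum_i (B/4)(theta^(m,n)_i - theta^0_i)**2`` times N, which is exactly
    zero for the target.  (A pure Helfrich density would miss the twist
    penalty of chiral competitors whose diameter is close to the target's.)
    """
    return N * bending_energy_per_monomer(TubuleIndices(*mn), kp.target, kp.B)


def closure_rate(mn: TubuleIndices, N: int, kp: KineticParams) -> float:
    """k_close^(m,n)(N) = k0_close * I * exp(-dG)."""
    ind = closure_indicator(mn, N, kp)
    if not ind:
        return 0.0
    return kp.k0_close * math.exp(-closure_barrier(mn, N, kp))

def total_closure_rate(N: int, kp: KineticParams, candidates) -> float:
    """Net closure rate: sum of the per-geometry rates."""
    return sum(closure_rate(mn, N, kp) for mn in candidates)


@dataclass
class ClosureTable:
    """Per-size ledger of the deterministic recursion."""

    kp: KineticParams
    sizes: np.ndarray  # N0 .. N_max
    dt: np.ndarray  # growth interval at each size
    t: np.ndarray  # cumulative time of first reaching each size
    P_open: np.ndarray  # probability still open on arriving at size N
    P_close: np.ndarray  # probability of closing while at size N
    P_mn: dict  # (m, n) -> total closure probability
    P_never: float  # mass still open at N_max

    @property
    def closed_fraction(self) -> float:
        return 1.0 - self.P_never

    def mean_D(self) -> float | None:
        """Mean diameter over closed geometries."""
        tot = sum(self.P_mn.values())
        if tot == 0:
            return None
        return (
            sum(p * diameter(TubuleIndices(*k), self.kp.lat) for k, p in self.P_mn.items())
            / tot
        )

    def delta_D(self) -> float | None:
        """Population std of the diameter over closed geometries."""
        tot = sum(self.P_mn.values())
        if tot == 0:
            return None
        mu = self.mean_D()
        var = (
            sum(
                p * (diameter(TubuleIndices(*k), self.kp.lat) - mu) ** 2
                for k, p in self.P_mn.items()
            )
            / tot
        )
        return math.sqrt(var)

    def mean_N_close(self) -> float | None:
        tot = float(self.P_close.sum())
        if tot == 0:
            return None
        return float((self.sizes * self.P_close).sum() / tot)


def solve_closure_table(kp: KineticParams, candidates=None) -> ClosureTable:
    """Integrate the growth-closure recursion from N0 to N_max.

    P_open(N+1) = P_open(N) exp(-k~(N) dt_N);
    P_close(N)  = P_open(N) (1 - exp(-k~(N) dt_N));
    P^(m,n)     = sum_N P_close(N) * k^(m,n)(N)/k~(N).
    Probability is conserved exactly: sum P^(m,n) + P_open(N_max) = 1.
    """
    if candidates is None:
        candidates = candidate_geometries(kp.target, lat=kp.lat)
    candidates = [TubuleIndices(*mn) for mn in candidates]
    sizes = np.arange(kp.N0, kp.N_max + 1)
    dt = np.array([1.0 / growth_rate(int(N), kp) for N in sizes])
    t = np.concatenate([[0.0], np.cumsum(dt[:-1])])
    P_open = np.empty(len(sizes))
    P_close = np.empty(len(sizes))
    P_mn = {(mn.m, mn.n): 0.0 for mn in candidates}
    p_open = 1.0
    for idx, N in enumerate(sizes):
        rates = [(mn, closure_rate(mn, int(N), kp)) for mn in candidates]
        ktot = sum(r for _, r in rates)
        P_open[idx] = p_open
        if ktot <= 0.0:
            P_close[idx] = 0.0
            continue
        surv = math.exp(-ktot * dt[idx])
        pc = p_open * (1.0 - surv)
        P_close[idx] = pc
        for mn, r in rates:
            if r > 0.0:
                P_mn[(mn.m, mn.n)] += pc * r / ktot
        p_open *= surv
    return ClosureTable(
        kp=kp,
        sizes=sizes,
        dt=dt,
        t=t,
        P_open=P_open,
        P_close=P_close,
        P_mn=P_mn,
        P_never=p_open,
    )


def gillespie_oracle(
    kp: KineticParams, candidates=None, n_trials: int = 10000, seed: int = 1
):
    """Continuous-time stochastic simulation of the same competing rates.

    Growth advances deterministically at intervals 1/k_grow(N) (as in the
    deterministic model); at each size a closure waiting time is drawn
    against the total closure rate.  Returns (P_mn dict, P_never).
    """
    if candidates is None:
        candidates = candidate_geometries(kp.target, lat=kp.lat)
    candidates = [TubuleIndices(*mn) for mn in candidates]
    rng = np.random.default_rng(seed)
    keys = [(mn.m, mn.n) for mn in candidates]
    counts = dict.fromkeys(keys, 0)
    never = 0
    sizes = range(kp.N0, kp.N_max + 1)
    rate_rows = []
    for N in sizes:
        rates = np.array([closure_rate(mn, N, kp) for mn in candidates])
        rate_rows.append((rates, float(rates.sum()), 1.0 / growth_rate(N, kp)))
    for _ in range(n_trials):
        fate = None
        for (rates, ktot, dtN) in rate_rows:
            if ktot > 0.0:
                if rng.random() < 1.0 - math.exp(-ktot * dtN):
                    fate = keys[rng.choice(len(rates), p=rates / ktot)]
                    break
        if fate is None:
            never += 1
        else:
            counts[fate] += 1
    P = {k: c / n_trials for k, c in counts.items()}
    return P, never / n_trials


def phase_map(
    target: TubuleIndices,
    B_values,
    log_kratio_values,
    N_max: int = 600,
    lat: LatticeConstants = LatticeConstants(),
):
    """Yield / closed-fraction / mean and CV of the width over a grid of
    bending modulus and normalised closure rate log10(k0_close/k0_grow).

    Returns a list of dict rows (suitable for a DataFrame).
    """
    target = TubuleIndices(*target)
    rows = []
    for B in B_values:
        cands = candidate_geometries(target, lat=lat)
        for lk in log_kratio_values:
            kp = KineticParams(
                target=target,
                B=B,
                k0_grow=1.0,
                k0_close=10.0**lk,
                N_max=N_max,
                lat=lat,
            )
            tab = solve_closure_table(kp, cands)
            mean_D = tab.mean_D()
            dD = tab.delta_D()
            rows.append(
                {
                    "B": B,
                    "log_kratio": lk,
                    "yield": tab.P_mn.get((target.m, target.n), 0.0),
                    "closed_fraction": tab.closed_fraction,
                    "mean_D": mean_D,
                    "delta_D": dD,
                    "cv_D": (dD / mean_D) if (mean_D and dD is not None) else None,
                    "mean_N_close": tab.mean_N_close(),
                }
            )
    return rows
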