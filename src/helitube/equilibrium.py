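"""Equilibrium theory of tubule geometry distributions.

Three levels of description:

* **Discrete model** — the free energy per monomer of an (m, n) tubule of
  length L,

      g^(m,n)_L = 2*gamma*a0/L - (3/2)*E_B
                  + sum_i (B/4) (theta^(m,n)_i - theta^0_i)**2 - T*s,

  (boundary line tension, bulk binding with three edges shared by two
  monomers, bending shared by two monomers per bound edge, per-monomer
  entropy).  With entropy taken geometry-independent the equilibrium
  geometry distribution is a Boltzmann distribution over the per-monomer
  bending energies, P ∝ exp[-N * sum_i (B/4) dtheta_i^2].

* **Continuum model** — Helfrich bending energy of a cylinder of diameter D,
  energy density (B~/2)(2/D - 2/D0)^2 per area, with B~ = (sqrt(3)/2) B the
  continuum modulus of the triangulated sheet.  Equipartition on the
  quadratic expansion gives the equilibrium width fluctuation
  dD/D0 = sqrt(kT * D0 / (4 pi B~ L)).

* **Einstein-crystal thermodynamic integration** — the absolute free energy
  of a closed tubule lattice at fixed topology, integrating
  <H - H_ref>_lambda along a linear path from an analytic Gaussian tether
  reference to the full Hamiltonian, with rigid-body modes removed by
  coordinate pinning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energetics import EnergyParams, NeighborhoodCache, total_energy
from .lattice import (
    LatticeConstants,
    TubuleIndices,
    diameter,
    ideal_dihedrals,
    ideal_embedding,
)
from .util import RandomPool

SQRT3 = math.sqrt(3.0)


# --------------------------------------------------------------------------
# bath arithmetic
# --------------------------------------------------------------------------

def bath_concentration(mu: float, c_SS: float = 10e-6) -> float:
    """Free monomer concentration c0 = c_SS * exp(mu / kT)."""
    if c_SS <= 0:
        raise ValueError("c_SS must be positive")
    return c_SS * math.exp(mu)

def chemical_potential(c0: float, c_SS: float = 10e-6) -> float:
    """Chemical potential mu = kT * ln(c0 / c_SS); inverse of
    :func:`bath_concentration`."""
    if c0 <= 0 or c_SS <= 0:
        raise ValueError("concentrations must be positive")
    return math.log(c0 / c_SS)

def bulk_free_energy_density(E_B: float, mu: float) -> float:
    """Net bulk free-energy density of an assembled tubule,
    de = -(3/2) E_B - mu (three bonds per monomer, each shared by two)."""
    return -1.5 * E_B - mu


# --------------------------------------------------------------------------
# discrete equilibrium model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteModelParams:
    """Inputs of the discrete per-monomer free energy."""

    target: TubuleIndices
    B: float = 20.0
    E_B: float = 6.0
    gamma: float = 0.0  # line tension, kT per l0
    s: float = 0.0  # per-monomer entropy, k_B
    L: float = math.inf  # tubule length, l0
    lat: LatticeConstants = LatticeConstants()


def bending_energy_per_monomer(
    mn: TubuleIndices, target: TubuleIndices, B: float
) -> float:
    """sum_i (B/4) (theta^(m,n)_i - theta^0_i)^2 — the per-monomer bending
    energy of geometry (m, n) with monomers programmed for ``target``."""
    th = ideal_dihedrals(TubuleIndices(*mn)).theta
    th0 = ideal_dihedrals(TubuleIndices(*target)).theta
    return sum(0.25 * B * (a - b) ** 2 for a, b in zip(th, th0))


def discrete_free_energy(mn: TubuleIndices, p: DiscreteModelParams) -> float:
    """Per-monomer free energy g^(m,n)_L of the discrete model (kT)."""
    g = -1.5 * p.E_B + bending_energy_per_monomer(mn, p.target, p.B) - p.s
    if math.isfinite(p.L):
        g += 2.0 * p.gamma * p.lat.a0 / p.L
    return g


def candidate_geometries(
    target: TubuleIndices, frac: float = 0.4, lat: LatticeConstants = LatticeConstants()
):
    """All (m, n) with diameter within ``+-frac`` of the target's, both
    chiralities (entries with n > m denote the mirror of (n, m))."""
    target = TubuleIndices(*target)
    D0 = diameter(target, lat)
    out = []
    mmax = int(math.ceil((1 + frac) * math.pi * D0 / lat.l0)) + 1
    for m in range(1, mmax + 1):
        for n in range(0, mmax + 1):
            if m < n and m == 0:
                continue
            try:
                mn = TubuleIndices(m, n)
            except ValueError:
                continue
            D = diameter(mn, lat)
            if abs(D - D0) <= frac * D0:
                out.append(mn)
    return out


def discrete_distribution(
    candidates, N: int, B: float, target: TubuleIndices
) -> dict:
    """Equilibrium probability of each candidate geometry for an N-monomer
    structure: P^(m,n) ∝ exp[-N * sum_i (B/4) dtheta_i^2]."""
    if not candidates:
        raise ValueError("empty candidate set")
    target = TubuleIndices(*target)
    logw = {}
    for mn in candidates:
        mn = TubuleIndices(*mn)
        logw[(mn.m, mn.n)] = -N * bending_energy_per_monomer(mn, target, B)
    mx = max(logw.values())
    w = {k: math.exp(v - mx) for k, v in logw.items()}
    z = sum(w.values())
    return {k: v / z for k, v in w.items()}


def distribution_at_length(
    target: TubuleIndices,
    L: float,
    B: float,
    candidates=None,
    lat: LatticeConstants = LatticeConstants(),
) -> dict:
    """Discrete equilibrium distribution evaluated at tubule length L: the
    monomer count of each candidate is N = pi*D*L/a0 (diameter-dependent)."""
    target = TubuleIndices(*target)
    if candidates is None:
        candidates = candidate_geometries(target, lat=lat)
    logw = {}
    for mn in candidates:
        mn = TubuleIndices(*mn)
        N = math.pi * diameter(mn, lat) * L / lat.a0
        logw[(mn.m, mn.n)] = -N * bending_energy_per_monomer(mn, target, B)
    mx = max(logw.values())
    w = {k: math.exp(v - mx) for k, v in logw.items()}
    z = sum(w.values())
    return {k: v / z for k, v in w.items()}


# --------------------------------------------------------------------------
# continuum model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContinuumParams:
    B_tilde: float
    D0: float
    L: float

    def __post_init__(self):
        if min(self.B_tilde, self.D0, self.L) <= 0:
            raise ValueError("continuum parameters must be positive")


def discrete_to_continuum_modulus(B: float) -> float:
    """Continuum bending modulus of the triangulated sheet,
    B~ = (sqrt(3)/2) B."""
    if B < 0:
        raise ValueError("B must be >= 0")
    return SQRT3 / 2.0 * B


def continuum_bend_density(D: float, c: ContinuumParams) -> float:
    """Helfrich bending-energy density (per area) of a cylinder of diameter
    D: (B~/2)(2/D - 2/D0)^2."""
    if D <= 0:
        raise ValueError("D must be positive")
    return 0.5 * c.B_tilde * (2.0 / D - 2.0 / c.D0) ** 2


def continuum_width_fluctuation(c: ContinuumParams, T: float = 1.0) -> float:
    """Equilibrium width fluctuation dD = D0 * sqrt(kT*D0/(4 pi B~ L))."""
    return c.D0 * math.sqrt(T * c.D0 / (4.0 * math.pi * c.B_tilde * c.L))


def equilibrium_delta_D(
    target: TubuleIndices, B: float, L: float, lat: LatticeConstants = LatticeConstants()
) -> float:
    """dD of the continuum model for a discrete-model tubule of length L."""
    c = ContinuumParams(
        B_tilde=discrete_to_continuum_modulus(B),
        D0=diameter(TubuleIndices(*target), lat),
        L=L,
    )
    return continuum_width_fluctuation(c)


# --------------------------------------------------------------------------
# thermodynamic integration
# --------------------------------------------------------------------------

@dataclass
class TIResult:
    """Free energy of a closed (m, n) tubule lattice from Einstein-crystal
    thermodynamic integration."""

    mn: TubuleIndices
    n_monomers: int
    n_bound_edges: int
    F_reference: float  # analytic Gaussian reference (kT)
    dF_path: float  # integral of <H_el - H_ref> over lambda
    dF_stderr: float
    E_bind: float  # -E_B * n_bound (constant at fixed topology)
    lambdas: list = field(default_factory=list)
    integrand: list = field(default_factory=list)
    integrand_se: list = field(default_factory=list)

    @property
    def F_elastic(self) -> float:
        return self.F_reference + self.dF_path

    @property
    def F_total(self) -> float:
        return self.F_elastic + self.E_bind

    @property
    def g(self) -> float:
        """Per-monomer free energy (kT)."""
        return self.F_total / self.n_monomers

    @property
    def g_elastic(self) -> float:
        return self.F_elastic / self.n_monomers

    @property
    def g_stderr(self) -> float:
        return self.dF_stderr / self.n_monomers


def thermodynamic_integration(
    mn: TubuleIndices,
    p: EnergyParams,
    rows: int = 6,
    seed: int = 1,
    n_nodes: int = 8,
    sweeps_eq: int = 200,
    sweeps_sample: int = 800,
    k_E: float = 100.0,
    delta_v: float = 0.12,
    lat: LatticeConstants = LatticeConstants(),
) -> TIResult:
    """Absolute free energy of a closed (m, n) tubule at fixed topology.

    The reference is an Einstein solid: every vertex tethered to its ideal
    position with spring constant ``k_E`` (chosen so reference fluctuations
    are comparable to those of the target Hamiltonian).  Rigid-body modes
    are removed by pinning six coordinates (one vertex fully, one to a line,
    one to a plane), in both the reference and the sampled system.  The path
    H_lambda = (1-lambda) H_ref + lambda H_el is integrated on a
    Gauss-Legendre grid; the binding energy is a topological constant and is
    added analytically.
    """
    mn = TubuleIndices(*mn)
    sheet = ideal_embedding(mn, rows=rows, lat=lat)
    x0 = {v: sheet.positions[v] for v in sheet.positions}
    n_bound = sheet.n_bound_edges
    N = sheet.n_triangles

    # pin: first triangle's vertices; (all, x&y, x) frozen coordinates
    t0 = next(iter(sheet.triangles))
    va, vb, vc = sheet.triangles[t0]
    frozen = {va: (True, True, True), vb: (True, True, False), vc: (True, False, False)}
    n_dof = 3 * sheet.n_vertices - 6

    F_ref = 0.5 * n_dof * math.log(k_E / (2.0 * math.pi))

    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    lambdas = 0.5 * (nodes + 1.0)
    weights = 0.5 * weights
    order = np.argsort(lambdas)
    lambdas, weights = lambdas[order], weights[order]

    rng = RandomPool(seed)
    cache = NeighborhoodCache(sheet, p)
    pos = sheet.positions
    vids = sorted(pos)

    def einstein_delta(vid, new):
        c = x0[vid]
        o = pos[vid]
        return 0.5 * k_E * (
            (new[0] - c[0]) ** 2
            + (new[1] - c[1]) ** 2
            + (new[2] - c[2]) ** 2
            - (o[0] - c[0]) ** 2
            - (o[1] - c[1]) ** 2
            - (o[2] - c[2]) ** 2
        )

    def einstein_energy():
        return 0.5 * k_E * sum(
            (pos[v][0] - x0[v][0]) ** 2
            + (pos[v][1] - x0[v][1]) ** 2
            + (pos[v][2] - x0[v][2]) ** 2
            for v in vids
        )

    def elastic_energy():
        br = total_energy(sheet, p)
        return br.E_stretch + br.E_bend

    def sweep(lam):
        for vid in vids:
            fz = frozen.get(vid)
            dx, dy, dz = rng.in_cube(delta_v)
            if fz is not None:
                if fz[0]:
                    dx = 0.0
                if fz[1]:
                    dy = 0.0
                if fz[2]:
                    dz = 0.0
                if dx == 0.0 and dy == 0.0 and dz == 0.0:
                    continue
            o = pos[vid]
            new = (o[0] + dx, o[1] + dy, o[2] + dz)
            dH = lam * cache.delta(vid, new) + (1.0 - lam) * einstein_delta(vid, new)
            if dH <= 0.0 or rng.u() < math.exp(-dH):
                pos[vid] = new

    means, ses = [], []
    for lam in lambdas:
        for _ in range(sweeps_eq):
            sweep(lam)
        samples = []
        for _ in range(sweeps_sample):
            sweep(lam)
            samples.append(elastic_energy() - einstein_energy())
        arr = np.asarray(samples)
        # few long blocks: the integrand decorrelates over ~100 sweeps, so
        # short blocks underestimate the error
        nblocks = max(6, min(10, len(arr) // 150))
        blocks = np.array_split(arr, nblocks)
        bm = np.array([b.mean() for b in blocks])
        means.append(float(arr.mean()))
        ses.append(float(bm.std(ddof=1) / math.sqrt(len(bm))))

    dF = float(np.dot(weights, means))
    dF_se = float(math.sqrt(np.dot(weights**2, np.array(ses) ** 2)))
    return TIResult(
        mn=mn,
        n_monomers=N,
        n_bound_edges=n_bound,
        F_reference=F_ref,
        dF_path=dF,
        dF_stderr=dF_se,
        E_bind=-p.E_B * n_bound,
        lambdas=list(map(float, lambdas)),
        integrand=means,
        integrand_se=ses,
    )


def critical_binding_energy(
    target: TubuleIndices,
    mu: float = -3.0,
    B: float = 20.0,
    rows: int = 6,
    seed: int = 1,
    **ti_kw,
) -> float:
    """Binding energy at which the bulk per-monomer free energy crosses mu.

    In the bulk each monomer carries 3/2 bonds, so g(E_B) = g_el - (3/2)E_B
    and the threshold is E_B* = (g_el - mu) / (3/2), with g_el the
    per-monomer elastic+vibrational free energy from thermodynamic
    integration of the target lattice.
    """
    target = TubuleIndices(*target)
    p = EnergyParams.for_target(target, B=B)
    res = thermodynamic_integration(target, p, rows=rows, seed=seed, **ti_kw)
    return (res.g_elastic - mu) / 1.5
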