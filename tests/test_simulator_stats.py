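"""Statistical-mechanics validation of the Monte Carlo engine.

Every test compares long-run chain statistics against an independent
analytic or quadrature oracle: single-triangle Boltzmann sampling,
grand-canonical dimer occupancy, equipartition on a fixed sheet, and
detailed-balance flow audits on enumerable micro-systems.
"""

import math

import numpy as np
import pytest

from helitube import (
    AssemblySimulator,
    BathConditions,
    EnergyParams,
    SimulationConfig,
    TubuleIndices,
    ideal_embedding,
    total_energy,
)
from helitube.mesh import TriangulatedSheet


def _edge_lengths(sheet):
    out = []
    for e in sheet.edges.values():
        out.append(math.dist(sheet.positions[e.u], sheet.positions[e.v]))
    return out


def _block_se(x, nblocks=20):
    blocks = np.array_split(np.asarray(x), nblocks)
    bm = np.array([b.mean() for b in blocks])
    return bm.std(ddof=1) / math.sqrt(len(bm))


class TestSingleTriangle:
    def test_edge_length_variance_matches_quadrature(self, params_10_0):
        # oracle: 3-vertex Boltzmann integral over shape space with the
        # bipolar measure  r12*r13*r23 dr12 dr13 dr23
        k = params_10_0.k_S
        r = np.linspace(0.7, 1.3, 401)
        w1 = r * np.exp(-0.5 * k * (r - 1.0) ** 2)
        # separable in the three lengths; moments of one edge
        m0 = np.trapezoid(w1, r)
        m1 = np.trapezoid(r * w1, r)
        m2 = np.trapezoid(r * r * w1, r)
        var_oracle = m2 / m0 - (m1 / m0) ** 2

        sim = AssemblySimulator(
            TubuleIndices(10, 0),
            params_10_0,
            cfg=SimulationConfig(seed=42, p_exchange=0.0, f_fusion=0.0),
        )
        samples = []
        for i in range(60000):
            sim.vertex_move()
            if i % 10 == 0 and i > 5000:
                samples.extend(_edge_lengths(sim.sheet))
        samples = np.asarray(samples)
        var = samples.var()
        # crude but conservative error bar on the variance
        se = 3.0 * _block_se((samples - samples.mean()) ** 2)
        assert abs(var - var_oracle) < max(se, 0.05 * var_oracle)


class TestDimerEquilibrium:
    def test_monomer_dimer_occupancy_matches_quadrature(self):
        """Grand-canonical monomer <-> dimer occupancy vs exact integrals.

        With the bipolar decomposition the configurational integrals
        factorise into 1-D integrals: Z1 = (I_r)^3 and, per binding type t,
        Z2_t = (I_r)^4 * I_0 * I_phi(t), with I_r = int r w(r) dr,
        I_0 = int w(r) dr, and I_phi the dihedral Boltzmann factor.  The
        labeled integral Z2_t counts each physical dimer twice (swapping the
        two identical monomers), so the physical ratio carries a symmetry
        factor 1/2 — monomers are indistinguishable, which is exactly the
        ensemble the uniform-selection exchange moves sample.
        """
        target = TubuleIndices(10, 0)
        p = EnergyParams.for_target(target, B=20.0, E_B=6.0)
        mu = -3.0
        k = p.k_S
        r = np.linspace(0.6, 1.4, 801)
        w = np.exp(-0.5 * k * (r - 1.0) ** 2)
        I_r = np.trapezoid(r * w, r)
        I_0 = np.trapezoid(w, r)
        phi = np.linspace(0.0, 2.0 * math.pi, 2001)
        Z2_over_Z1 = 0.0
        for t in (1, 2, 3):
            I_phi = np.trapezoid(np.exp(-0.5 * p.B * (phi - p.theta0[t]) ** 2), phi)
            Z2_over_Z1 += (I_r**4 * I_0 * I_phi) / (I_r**3)
        ratio_oracle = math.exp(mu + p.E_B) * Z2_over_Z1 / 2.0
        p2_oracle = ratio_oracle / (1.0 + ratio_oracle)

        cfg = SimulationConfig(
            seed=7, p_exchange=0.5, f_fusion=0.0, max_sweeps=np.inf
        )
        sim = AssemblySimulator(target, p, BathConditions(mu=mu), cfg)

        # cap the system at N <= 2 (symmetric rejection keeps detailed balance)
        orig = sim.attempt_association

        def capped():
            if sim.sheet.n_triangles >= 2:
                return False
            return orig()

        sim.attempt_association = capped
        occ = []
        for i in range(400000):
            sim.step()
            if i > 20000 and i % 5 == 0:
                occ.append(1.0 if sim.sheet.n_triangles == 2 else 0.0)
        occ = np.asarray(occ)
        p2 = occ.mean()
        se = _block_se(occ)
        assert abs(p2 - p2_oracle) < 3.0 * max(se, 0.01)


class TestEquipartition:
    def test_fixed_sheet_energy_fluctuation(self, params_10_0):
        # vertex moves only on a fixed topology: <E - E_min> = n_dof/2 kT
        sheet = ideal_embedding(TubuleIndices(6, 0), rows=4)
        sim = AssemblySimulator(
            TubuleIndices(6, 0),
            EnergyParams.for_target(TubuleIndices(6, 0)),
            cfg=SimulationConfig(seed=3, p_exchange=0.0, f_fusion=0.0, delta_v=0.08),
            sheet=sheet,
        )
        p = sim.p
        V = sheet.n_vertices
        n_dof = 3 * V - 6
        samples = []
        for i in range(1200 * V):
            sim.vertex_move()
            if i > 200 * V and i % V == 0:
                br = total_energy(sheet, p)
                samples.append(br.E_stretch + br.E_bend)
        mean = float(np.mean(samples))
        # harmonic expectation; mild anharmonicity allowed within 5%
        assert mean == pytest.approx(0.5 * n_dof, rel=0.05)


class TestDetailedBalance:
    def test_exchange_flow_balance_micro_system(self, params_10_0):
        """On a <=3-monomer system, stationarity implies equal numbers of
        accepted insertions and deletions (flows balance between levels)."""
        cfg = SimulationConfig(
            seed=11, p_exchange=0.5, f_fusion=0.05, max_sweeps=np.inf
        )
        sim = AssemblySimulator(
            TubuleIndices(10, 0), params_10_0, BathConditions(mu=-3.0), cfg
        )
        orig = sim.attempt_association

        def capped():
            if sim.sheet.n_triangles >= 3:
                return False
            return orig()

        sim.attempt_association = capped
        for _ in range(500000):
            sim.step()
        kinds = [k for _, k in sim.record.events]
        n_ins = kinds.count("insert")
        n_del = kinds.count("delete")
        n_fus = kinds.count("fuse")
        n_fis = kinds.count("fission")
        assert n_ins + n_del > 200  # enough events to be meaningful
        assert abs(n_ins - n_del) <= max(3.0 * math.sqrt(n_ins + n_del), 3)
        assert abs(n_fus - n_fis) <= max(3.0 * math.sqrt(n_fus + n_fis + 1), 3)
        sim.sheet.check_invariants()

    def test_trajectory_determinism(self, params_10_0):
        cfgs = [
            SimulationConfig(seed=5, max_sweeps=300, record_every=50)
            for _ in range(2)
        ]
        recs = [
            AssemblySimulator(TubuleIndices(6, 0),
                              EnergyParams.for_target(TubuleIndices(6, 0)),
                              cfg=c).run()
            for c in cfgs
        ]
        assert recs[0].events == recs[1].events
        assert recs[0].series == recs[1].series
        assert recs[0].n_attempts == recs[1].n_attempts

    def test_zero_displacement_always_accepted(self, params_10_0):
        sim = AssemblySimulator(
            TubuleIndices(10, 0),
            params_10_0,
            cfg=SimulationConfig(seed=1, delta_v=0.0),
        )
        assert all(sim.vertex_move() for _ in range(50))

    def test_mu_minus_infinity_no_growth(self, params_10_0):
        cfg = SimulationConfig(seed=2, p_exchange=0.5, f_fusion=0.0, max_sweeps=np.inf)
        sim = AssemblySimulator(
            TubuleIndices(10, 0), params_10_0, BathConditions(mu=-40.0), cfg
        )
        for _ in range(30000):
            sim.step()
        assert sim.sheet.n_triangles == 1
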