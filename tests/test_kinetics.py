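"""Growth-closure kinetic model: rates, recursion, oracle agreement."""

import math

import numpy as np
import pytest

from helitube import (
    KineticParams,
    TubuleIndices,
    closure_indicator,
    closure_rate,
    gillespie_oracle,
    growth_rate,
    phase_map,
    solve_closure_table,
    total_closure_rate,
)
from helitube.kinetics import closure_barrier, disk_perimeter


@pytest.fixture(scope="module")
def kp10():
    return KineticParams(target=TubuleIndices(10, 0), B=20.0, k0_close=0.1, N_max=500)


class TestGrowthRate:
    def test_sqrt_N_proportionality(self, kp10):
        assert growth_rate(400, kp10) == pytest.approx(2 * growth_rate(100, kp10))

    def test_single_monomer_value(self, kp10):
        # 2*sqrt(pi*a0) with a0 = sqrt(3)/4
        assert growth_rate(1, kp10) == pytest.approx(
            2.0 * math.sqrt(math.pi * math.sqrt(3) / 4.0)
        )
        assert growth_rate(1, kp10) == pytest.approx(2.3327, abs=1e-4)

    def test_growth_intervals_decrease(self, kp10):
        dts = [1.0 / growth_rate(N, kp10) for N in range(1, 50)]
        assert all(a > b for a, b in zip(dts, dts[1:]))


class TestClosureIndicator:
    def test_single_monomer_closed_to_none(self, kp10):
        for m in range(2, 12):
            assert closure_indicator(TubuleIndices(m, 0), 1, kp10) == 0

    def test_monotone_in_N(self, kp10):
        prev = 0
        for N in range(1, 400):
            cur = closure_indicator(TubuleIndices(10, 0), N, kp10)
            assert cur >= prev
            prev = cur

    def test_threshold_brute_force(self, kp10):
        # smallest N with 2*sqrt(N*a0/pi) >= 10
        a0 = math.sqrt(3) / 4.0
        N_star = next(
            N for N in range(1, 1000) if 2 * math.sqrt(N * a0 / math.pi) >= 10.0
        )
        assert N_star == 182
        assert closure_indicator(TubuleIndices(10, 0), 181, kp10) == 0
        assert closure_indicator(TubuleIndices(10, 0), 182, kp10) == 1


class TestClosureRates:
    def test_target_has_zero_barrier(self, kp10):
        N = 200
        assert closure_barrier(TubuleIndices(10, 0), N, kp10) == 0.0
        assert closure_rate(TubuleIndices(10, 0), N, kp10) == pytest.approx(
            kp10.k0_close
        )

    def test_stiff_limit_kills_off_target(self):
        kp = KineticParams(target=TubuleIndices(10, 0), B=1e5, k0_close=1.0, N_max=400)
        N = 200
        assert closure_rate(TubuleIndices(9, 0), N, kp) < 1e-30
        total = total_closure_rate(N, kp, [TubuleIndices(9, 0), TubuleIndices(10, 0)])
        assert total == pytest.approx(closure_rate(TubuleIndices(10, 0), N, kp))

    def test_total_is_hand_sum(self, kp10):
        cands = [TubuleIndices(9, 0), TubuleIndices(10, 0), TubuleIndices(11, 0)]
        N = 250
        assert total_closure_rate(N, kp10, cands) == pytest.approx(
            sum(closure_rate(mn, N, kp10) for mn in cands)
        )


class TestClosureTable:
    def test_probability_conservation(self, kp10):
        tab = solve_closure_table(kp10)
        total = sum(tab.P_mn.values()) + tab.P_never
        assert abs(total - 1.0) < 1e-12

    def test_constant_rate_closed_form(self):
        # single candidate whose indicator is 1 from the start, constant
        # growth rate: geometric-like closure-size distribution
        kp = KineticParams(target=TubuleIndices(3, 0), B=20.0, k0_close=0.5,
                           N0=20, N_max=120)
        cands = [TubuleIndices(3, 0)]
        tab = solve_closure_table(kp, cands)
        p_open = 1.0
        for idx, N in enumerate(tab.sizes):
            k = kp.k0_close  # zero barrier for the target
            surv = math.exp(-k * tab.dt[idx])
            assert tab.P_close[idx] == pytest.approx(p_open * (1 - surv), rel=1e-12)
            p_open *= surv

    def test_fast_closure_limit(self):
        # with no bending barriers (B=0), an infinitely fast closure rate
        # closes every structure at the first size with any indicator on
        kp = KineticParams(target=TubuleIndices(6, 0), B=0.0, k0_close=1e9, N_max=300)
        tab = solve_closure_table(kp)
        assert tab.closed_fraction == pytest.approx(1.0, abs=1e-9)
        first = next(idx for idx, _ in enumerate(tab.sizes) if tab.P_close[idx] > 0)
        assert tab.P_close[first] == pytest.approx(1.0)

    def test_slow_closure_limit(self):
        kp = KineticParams(target=TubuleIndices(6, 0), B=20.0, k0_close=1e-9, N_max=300)
        tab = solve_closure_table(kp)
        assert tab.P_never == pytest.approx(1.0, abs=1e-4)

    def test_N0_independence_before_threshold(self):
        base = dict(target=TubuleIndices(8, 0), B=20.0, k0_close=0.3, N_max=400)
        t1 = solve_closure_table(KineticParams(N0=1, **base))
        t2 = solve_closure_table(KineticParams(N0=30, **base))
        for k in t1.P_mn:
            assert t1.P_mn[k] == pytest.approx(t2.P_mn[k], abs=1e-12)

    def test_gillespie_agreement(self, kp10):
        tab = solve_closure_table(kp10)
        n_trials = 20000
        P, never = gillespie_oracle(kp10, n_trials=n_trials, seed=9)
        tv = 0.5 * (
            sum(abs(P[k] - tab.P_mn[k]) for k in tab.P_mn) + abs(never - tab.P_never)
        )
        assert tv < 3.0 / math.sqrt(n_trials)

    def test_gillespie_reproducible(self, kp10):
        a = gillespie_oracle(kp10, n_trials=2000, seed=5)
        b = gillespie_oracle(kp10, n_trials=2000, seed=5)
        assert a == b


class TestPhaseMap:
    def test_mean_width_decreases_with_closure_rate(self):
        rows = phase_map((10, 0), [20.0], [-2.0, -1.0, 0.0, 1.0], N_max=500)
        means = [r["mean_D"] for r in rows]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_closed_fraction_increases_with_rate(self):
        rows = phase_map((10, 0), [20.0], [-3.0, -2.0, -1.0, 0.0], N_max=500)
        fr = [r["closed_fraction"] for r in rows]
        assert all(a < b for a, b in zip(fr, fr[1:]))

    def test_cv_decreases_with_B(self):
        rows = phase_map((10, 0), [10.0, 20.0, 50.0], [0.0], N_max=500)
        cvs = [r["cv_D"] for r in rows]
        assert cvs[0] > cvs[1] > cvs[2]
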