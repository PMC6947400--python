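"""Exact M/M/R/N steady-state analysis: closed form vs. dense-solve oracle,
textbook limiting cases, and conservation-law invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edqueue import (
    QueueParams,
    birth_death_rates,
    oracle_stationary,
    performance_measures,
    random_scenarios,
    stationary_distribution,
)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(R=0, N=5, lam=1, mu=1),
            dict(R=3, N=2, lam=1, mu=1),
            dict(R=1, N=1, lam=0, mu=1),
            dict(R=1, N=1, lam=1, mu=-2),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            QueueParams(**kwargs)

    def test_overload_permitted(self):
        # finite capacity keeps the chain ergodic even at rho_s > 1
        p = QueueParams(R=1, N=15, lam=3.5, mu=1)
        assert p.rho_s == pytest.approx(3.5)
        assert np.isfinite(stationary_distribution(p).probs).all()


class TestBirthDeathRates:
    @pytest.mark.parametrize(
        "n, expected_lam, expected_mu",
        [
            (0, 2.0, 0.0),  # empty: no service
            (2, 2.0, 2.0),  # below R: one server per patient
            (4, 2.0, 4.0),  # all R servers busy
            (5, 0.0, 4.0),  # full: admissions stop, service capped at R*mu
        ],
    )
    def test_rates(self, ex_small, n, expected_lam, expected_mu):
        lam_n, mu_n = birth_death_rates(ex_small, n)
        assert lam_n == expected_lam
        assert mu_n == expected_mu

    @pytest.mark.parametrize("n", [-1, 6, 2.5])
    def test_out_of_domain(self, ex_small, n):
        with pytest.raises(ValueError):
            birth_death_rates(ex_small, n)


class TestStationaryDistribution:
    def test_worked_example_coefficients(self, ex_small):
        # relative to P(0): [1, 2, 2, 4/3, 2/3, 1/3]; P(0) = 3/22
        dist = stationary_distribution(ex_small)
        ratios = dist.probs / dist.p0
        np.testing.assert_allclose(
            ratios, [1, 2, 2, 4 / 3, 2 / 3, 1 / 3], rtol=1e-12
        )
        assert dist.p0 == pytest.approx(3 / 22, abs=1e-14)
        assert round(dist.p0, 3) == 0.136

    def test_two_state_chain(self):
        dist = stationary_distribution(QueueParams(R=1, N=1, lam=1.3, mu=1.3))
        np.testing.assert_allclose(dist.probs, [0.5, 0.5], atol=1e-14)

    def test_matches_oracle_small(self):
        p = QueueParams(R=2, N=4, lam=3, mu=2)
        np.testing.assert_allclose(
            stationary_distribution(p).probs,
            oracle_stationary(p).probs,
            atol=1e-12,
        )

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        R=st.integers(1, 20),
        extra=st.integers(0, 180),
        rho_s=st.one_of(st.just(1.0), st.floats(0.01, 3.0)),
        mu=st.floats(0.1, 10.0),
    )
    def test_closed_form_equals_oracle(self, R, extra, rho_s, mu):
        p = QueueParams(R=R, N=R + extra, lam=rho_s * R * mu, mu=mu)
        closed = stationary_distribution(p).probs
        dense = oracle_stationary(p).probs
        assert abs(closed.sum() - 1) < 1e-12
        np.testing.assert_allclose(closed, dense, atol=1e-10)

    def test_erlang_b_limit(self):
        # zero waiting buffer: blocking equals the Erlang-B loss formula
        for R, rho in [(1, 0.5), (3, 2.0), (8, 8.0), (5, 15.0)]:
            p = QueueParams(R=R, N=R, lam=rho, mu=1.0)
            terms = [rho**k / math.factorial(k) for k in range(R + 1)]
            erlang_b = terms[-1] / sum(terms)
            m = performance_measures(p)
            assert m.P_block == pytest.approx(erlang_b, abs=1e-12)
            assert m.Lq == pytest.approx(0.0, abs=1e-14)
            assert m.Wq == 0.0

    @pytest.mark.parametrize("rho", [0.3, 0.99, 1.7, 3.5])
    def test_single_server_truncated_geometric(self, rho):
        N = 15
        p = QueueParams(R=1, N=N, lam=rho, mu=1.0)
        expected = rho ** np.arange(N + 1) * (1 - rho) / (1 - rho ** (N + 1))
        np.testing.assert_allclose(
            stationary_distribution(p).probs, expected, atol=1e-12
        )


class TestPerformanceMeasures:
    def test_worked_example_exact_values(self, ex_small):
        m = performance_measures(ex_small)
        assert m.Ls == pytest.approx(43 / 22, abs=1e-12)  # 1.9545...
        assert m.Lq == pytest.approx(1 / 22, abs=1e-12)  # 0.04545...
        assert m.EI == pytest.approx(46 / 22, abs=1e-12)  # 2.0909...
        assert m.EB == pytest.approx(4 - 46 / 22, abs=1e-12)
        assert m.PB == pytest.approx(3 / 22, abs=1e-12)
        assert round(m.PB, 3) == 0.136
        assert m.Ws == pytest.approx(m.Ls / 2, abs=1e-14)
        assert m.Wq == pytest.approx(m.Lq / 2, abs=1e-14)

    def test_reference_row_R6(self):
        # values behind the R=6 row of the reference staffing table,
        # certified against the dense-solve oracle
        p = QueueParams(R=6, N=15, lam=3.5, mu=1.0)
        P = oracle_stationary(p).probs
        n = np.arange(16)
        lq_oracle = float((n[6:] - 6) @ P[6:])
        ei_oracle = float((6 - n[:6]) @ P[:6])
        m = performance_measures(p)
        assert m.Lq == pytest.approx(lq_oracle, abs=1e-12)
        assert m.EI == pytest.approx(ei_oracle, abs=1e-12)
        assert m.Lq == pytest.approx(0.2394, abs=1e-4)
        assert m.EB == pytest.approx(3.4979, abs=1e-4)
        assert m.EI == pytest.approx(2.5021, abs=1e-4)

    def test_no_waiting_room_means_no_queue(self):
        m = performance_measures(QueueParams(R=3, N=3, lam=7.7, mu=0.9))
        assert m.Lq == 0.0
        assert m.Wq == 0.0

    def test_conservation_invariants_on_random_scenarios(self):
        for p in random_scenarios(seed=7, count=100):
            m = performance_measures(p)
            assert m.Ls == pytest.approx(m.Lq + m.EB, abs=1e-10)
            assert m.EB + m.EI == pytest.approx(p.R, abs=1e-10)
            # flow conservation: service throughput equals accepted arrivals
            assert m.EB * p.mu == pytest.approx(
                p.lam * (1 - m.P_block), abs=1e-10 * max(1, p.lam)
            )
            assert 0 <= m.PB <= 1
            assert m.Lq <= p.N - p.R + 1e-12
            assert m.Ls <= p.N + 1e-12
            assert m.lam_eff == pytest.approx(p.lam * (1 - m.P_block))

    def test_measures_monotone_in_provider_count(self):
        # more providers never worsen congestion, all else fixed
        prev = None
        for R in range(1, 13):
            m = performance_measures(QueueParams(R=R, N=15, lam=3.5, mu=1.0))
            if prev is not None:
                assert m.Lq <= prev.Lq + 1e-12
                assert m.Wq <= prev.Wq + 1e-12
                assert m.PB <= prev.PB + 1e-12
                assert m.P_block <= prev.P_block + 1e-12
            prev = m

    def test_continuity_at_critical_load(self):
        # rho_s = 1 is a removable singularity of the geometric closed form;
        # the recursion must be smooth through it
        R, N, mu = 4, 20, 1.0
        at = performance_measures(QueueParams(R=R, N=N, lam=R * mu, mu=mu))
        for sign in (-1, 1):
            near = performance_measures(
                QueueParams(R=R, N=N, lam=R * mu * (1 + sign * 1e-9), mu=mu)
            )
            for attr in ("Ls", "Lq", "PB", "P_block", "EB", "EI", "Ws", "Wq"):
                assert getattr(near, attr) == pytest.approx(
                    getattr(at, attr), abs=1e-6
                )
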