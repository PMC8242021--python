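"""Accountant unit and property tests.

Frozen expected values are direct evaluations of the closed-form GDP/RDP
expressions (computed independently by hand / with tabulated normal CDF
values); the RDP binomial sum is additionally checked against an
exact-arithmetic brute-force oracle.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import norm

import privgrad as pg
from hypothesis import given, settings, strategies as st

from privgrad.accounting import InvalidScheduleError, DEFAULT_RDP_ORDERS

CLS = dict(n=4389, batch_size=32, noise_multiplier=3.0, delta=1e-5, epochs=20)
SEG = dict(n=5184, batch_size=32, noise_multiplier=5.0, delta=1e-5, epochs=5)


@pytest.mark.parametrize("n,B,E,expected", [
    (5184, 32, 5, 810),       # exact division: 5 * 162
    (4389, 32, 20, 2760),     # 20 * ceil(137.16) = 20 * 138
    (10, 10, 0, 0),           # zero epochs
])
def test_steps_from_epochs(n, B, E, expected):
    assert pg.steps_from_epochs(n, B, E) == expected


def test_steps_from_epochs_rejects_bad_sizes():
    with pytest.raises(InvalidScheduleError):
        pg.steps_from_epochs(0, 1, 1)
    with pytest.raises(InvalidScheduleError):
        pg.steps_from_epochs(10, 0, 1)
    with pytest.raises(InvalidScheduleError):
        pg.steps_from_epochs(10, 32, 1)  # B > n


def test_schedule_derives_steps_and_rate():
    s = pg.TrainingSchedule(**SEG)
    assert s.total_steps == 810
    assert s.sample_rate == 32 / 5184
    with pytest.raises(InvalidScheduleError):
        pg.TrainingSchedule(n=10, batch_size=2, noise_multiplier=-1.0,
                            delta=1e-5, epochs=1)
    with pytest.raises(InvalidScheduleError):
        pg.TrainingSchedule(n=10, batch_size=2, noise_multiplier=1.0,
                            delta=2.0, epochs=1)


class TestMu:
    def test_poisson_single_step_full_batch(self):
        s = pg.TrainingSchedule(n=4, batch_size=4, noise_multiplier=1.0,
                                delta=1e-5, total_steps=1)
        assert pg.compute_mu_poisson(s) == pytest.approx(math.sqrt(math.e - 1),
                                                         abs=1e-12)

    def test_zero_steps_gives_zero_mu(self):
        s = pg.TrainingSchedule(**SEG)
        assert pg.compute_mu_poisson(s, steps=0) == 0.0
        assert pg.compute_mu_uniform(s, steps=0) == 0.0

    def test_segmentation_mu_value(self):
        # q=32/5184, T=810, sigma=5: mu = q*sqrt(T*(e^{1/25}-1)) = 0.035491
        s = pg.TrainingSchedule(**SEG)
        assert pg.compute_mu_poisson(s) == pytest.approx(0.0354907, abs=1e-6)

    def test_uniform_single_step(self):
        # sqrt(e^{1/9} Phi(0.5) + 3 Phi(-1/6) - 2) = 0.27235
        s = pg.TrainingSchedule(n=4, batch_size=4, noise_multiplier=3.0,
                                delta=1e-5, total_steps=1)
        assert pg.compute_mu_uniform(s) == pytest.approx(0.2723, abs=1e-3)

    def test_mu_vanishes_for_huge_sigma(self):
        for sigma in (1e3, 1e6):
            s = pg.TrainingSchedule(n=100, batch_size=10,
                                    noise_multiplier=sigma, delta=1e-5,
                                    total_steps=100)
            assert pg.compute_mu_poisson(s) < 1e-2
            assert pg.compute_mu_uniform(s) < 1e-2


class TestGaussianDual:
    def test_delta_at_eps_zero(self):
        # closed form at eps=0: delta = Phi(mu/2) - Phi(-mu/2)
        assert pg.delta_from_eps_mu(0.0, 1.0) == pytest.approx(0.38292, abs=1e-5)

    def test_degenerate_cases(self):
        assert pg.delta_from_eps_mu(0.0, 0.0) == 0.0
        assert pg.delta_from_eps_mu(500.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert pg.eps_from_delta_mu(0.5, 0.0) == 0.0

    def test_round_trip_identity_on_grid(self):
        for eps in np.linspace(0.0, 5.0, 11):
            for mu in np.linspace(0.25, 5.0, 10):
                delta = pg.delta_from_eps_mu(eps, mu)
                if delta <= 0:
                    continue
                back = pg.eps_from_delta_mu(delta, mu)
                assert back == pytest.approx(eps, abs=1e-5)

    def test_delta_monotone_in_eps_and_mu(self):
        eps_grid = np.linspace(0.0, 3.0, 20)
        deltas = [pg.delta_from_eps_mu(e, 1.5) for e in eps_grid]
        assert all(a > b for a, b in zip(deltas, deltas[1:]))
        mu_grid = np.linspace(0.1, 4.0, 20)
        deltas = [pg.delta_from_eps_mu(0.5, m) for m in mu_grid]
        assert all(a < b for a, b in zip(deltas, deltas[1:]))

    def test_round_trip_and_segmentation_epsilon(self):
        # mu = 0.0355 at delta 1e-5 certifies eps around 0.11
        eps = pg.eps_from_delta_mu(1e-5, 0.0355)
        assert eps == pytest.approx(0.11, abs=0.01)
        delta_back = pg.delta_from_eps_mu(eps, 0.0355)
        assert 1e-5 * (1 - 1e-3) <= delta_back <= 1e-5 * (1 + 1e-9)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(eps=st.floats(0.0, 5.0), mu=st.floats(0.05, 5.0))
def test_dual_round_trip_property(eps, mu):
    """eps_from_delta_mu inverts delta_from_eps_mu wherever delta is
    representable."""
    delta = pg.delta_from_eps_mu(eps, mu)
    if delta > 1e-300:
        assert pg.eps_from_delta_mu(delta, mu) == pytest.approx(eps, abs=1e-5)


def _rdp_bruteforce(q, sigma, alpha):
    """Exact-arithmetic binomial sum (Fractions; exp at full float precision)."""
    total = 0.0
    for k in range(alpha + 1):
        comb = math.comb(alpha, k)
        prob = Fraction(1 - Fraction(q)) ** (alpha - k) * Fraction(q) ** k
        total += comb * float(prob) * math.exp(k * (k - 1) / (2 * sigma**2))
    return math.log(total) / (alpha - 1)


class TestRdp:
    def test_no_subsampling_reduces_to_gaussian(self):
        curve = pg.rdp_sampled_gaussian(1.0, 1.0, orders=range(2, 17))
        for a, e in zip(curve.orders, curve.eps_per_step):
            assert e == pytest.approx(a / 2.0, rel=1e-12)

    def test_zero_rate_spends_nothing(self):
        curve = pg.rdp_sampled_gaussian(0.0, 2.0, orders=[2, 8, 32])
        assert all(e == 0.0 for e in curve.eps_per_step)

    @pytest.mark.parametrize("q,sigma", [(0.01, 2.0), (0.1, 1.0), (0.5, 3.0)])
    def test_matches_bruteforce_oracle(self, q, sigma):
        orders = list(range(2, 17))
        curve = pg.rdp_sampled_gaussian(q, sigma, orders)
        for a, e in zip(orders, curve.eps_per_step):
            assert e == pytest.approx(_rdp_bruteforce(q, sigma, a),
                                      rel=1e-9, abs=1e-12)

    def test_conversion_zero_steps(self):
        curve = pg.rdp_sampled_gaussian(0.1, 2.0, orders=[2, 16, 256])
        eps, best = pg.eps_from_rdp(curve, 0, 1e-5)
        assert best == 256
        assert eps == pytest.approx(math.log(1e5) / 255)

    def test_conversion_single_order(self):
        curve = pg.RdpCurve(orders=(2,), eps_per_step=(1.0,))
        eps, best = pg.eps_from_rdp(curve, 1, math.exp(-1))
        assert eps == pytest.approx(2.0)
        assert best == 2

    def test_empty_curve_rejected(self):
        with pytest.raises(pg.AccountingError):
            pg.eps_from_rdp(pg.RdpCurve((), ()), 1, 1e-5)

    def test_log_space_survives_naive_overflow(self):
        # naive term e^{k(k-1)/(2 sigma^2)} overflows float64 at alpha=256,
        # sigma=0.5; the log-space sum must still be finite and positive
        curve = pg.rdp_sampled_gaussian(0.01, 0.5, orders=[256])
        assert math.isfinite(curve.eps_per_step[0])
        assert curve.eps_per_step[0] > 0


class TestAudit:
    def test_segmentation_budget_reproduced(self):
        spent = pg.audit(pg.TrainingSchedule(**SEG), "gdp-poisson")
        assert spent.epsilon <= 0.12
        assert spent.mode == "gdp-poisson"

    def test_zero_steps_zero_epsilon(self):
        for mode in ("gdp-poisson", "gdp-uniform"):
            assert pg.audit(pg.TrainingSchedule(**CLS), mode, steps=0).epsilon == 0.0

    def test_epsilon_monotone_in_steps_rate_sigma(self):
        s = pg.TrainingSchedule(**CLS)
        eps_steps = [pg.audit(s, steps=t).epsilon for t in (100, 500, 1000, 2760)]
        assert all(a < b for a, b in zip(eps_steps, eps_steps[1:]))
        # larger batch = larger q = more spent
        eps_q = [
            pg.audit(pg.TrainingSchedule(n=4389, batch_size=b,
                                         noise_multiplier=3.0, delta=1e-5,
                                         total_steps=1000)).epsilon
            for b in (16, 32, 64, 128)
        ]
        assert all(a < b for a, b in zip(eps_q, eps_q[1:]))
        # doubling sigma strictly reduces epsilon
        doubled = pg.TrainingSchedule(n=4389, batch_size=32,
                                      noise_multiplier=6.0, delta=1e-5, epochs=20)
        assert pg.audit(doubled).epsilon < pg.audit(s).epsilon

    def test_gdp_tighter_than_rdp_on_both_schedules(self):
        for kw in (CLS, SEG):
            s = pg.TrainingSchedule(**kw)
            assert pg.audit(s, "gdp-poisson").epsilon < pg.audit(s, "rdp").epsilon

    def test_rdp_mode_reports_best_order(self):
        spent = pg.audit(pg.TrainingSchedule(**CLS), "rdp")
        assert spent.best_order in DEFAULT_RDP_ORDERS
        assert spent.epsilon > 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(pg.AccountingError):
            pg.audit(pg.TrainingSchedule(**CLS), "moments")
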