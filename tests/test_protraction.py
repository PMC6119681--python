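"""Lea-Catcheside protraction factor, critical thresholds, extended LQ."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from rntlq import constants as C
from rntlq import dosimetry as dm
from rntlq import protraction as pk
from rntlq.errors import DomainError, NeverEffectiveError
from rntlq.protraction import CellLineRadioParams, RepairKinetics


def g_exponential_oracle(lam: float, mu: float, T: float) -> float:
    """Brute-force nested quadrature of the protraction integral for an
    exponentially decaying dose rate starting at t = 0."""
    dose, _ = quad(lambda t: math.exp(-lam * t), 0.0, T)

    def inner(t):
        val, _ = quad(lambda tp: math.exp(-lam * tp - mu * (t - tp)), 0.0, t)
        return val

    outer, _ = quad(lambda t: math.exp(-lam * t) * inner(t), 0.0, T, limit=200)
    return 2.0 * outer / dose**2


def g_constant_oracle(dose: float, rate: float, mu: float) -> float:
    T = dose / rate

    def inner(t):
        val, _ = quad(lambda tp: rate * math.exp(-mu * (t - tp)), 0.0, t)
        return val

    outer, _ = quad(lambda t: rate * inner(t), 0.0, T, limit=200)
    return 2.0 * outer / dose**2


class TestLeaCatchesideExponential:
    def test_no_repair_is_exactly_one(self):
        for lam, T in [(0.01, 10.0), (0.5, 300.0), (1.0, 1.0)]:
            assert pk.lea_catcheside_G(lam, 0.0, T) == 1.0

    def test_matches_double_integral_oracle(self, rng):
        for _ in range(12):
            lam = 10 ** rng.uniform(-3, 0)
            mu = 10 ** rng.uniform(-3, 1)
            T = rng.uniform(1.0, 400.0)
            g = pk.lea_catcheside_G(lam, mu, T)
            assert g == pytest.approx(g_exponential_oracle(lam, mu, T), rel=1e-6)

    @pytest.mark.parametrize("eps", [0.0, 1e-9, 1e-7, 1e-5, 1e-3])
    def test_continuity_at_equal_rates(self, eps):
        lam, T = 0.05, 100.0
        mu = lam * (1.0 + eps)
        g = pk.lea_catcheside_G(lam, mu, T)
        assert g == pytest.approx(g_exponential_oracle(lam, mu, T), rel=1e-6)

    def test_long_exposure_converges_to_asymptote(self):
        lam = 0.0107
        mu = C.LN2 / 1.5
        g = pk.lea_catcheside_G(lam, mu, 20.0 / lam)
        ginf = pk.g_infinity(C.LN2 / lam, 1.5)
        assert g == pytest.approx(ginf, rel=1e-3)
        assert g == pytest.approx(0.0226, abs=2e-4)

    @given(
        lam=st.floats(1e-3, 1.0),
        mu=st.floats(1e-3, 5.0),
        T=st.floats(0.5, 500.0),
    )
    def test_bounded_and_monotone(self, lam, mu, T):
        g = pk.lea_catcheside_G(lam, mu, T)
        assert 0.0 < g <= 1.0
        assert pk.lea_catcheside_G(lam, mu * 1.5, T) <= g + 1e-12
        assert pk.lea_catcheside_G(lam, mu, T * 1.5) <= g + 1e-12

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(DomainError):
            pk.lea_catcheside_G(0.0, 0.1, 10.0)


class TestLeaCatchesideConstantRate:
    def test_acute_limit(self):
        assert pk.lea_catcheside_G_constant_rate(1.0, 1e9, 0.46) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_external_beam_exposure_is_effectively_unprotracted(self):
        g = pk.lea_catcheside_G_constant_rate(8.0, 277.0, C.LN2 / 1.5)
        assert g == pytest.approx(1.0, rel=0.01)

    def test_matches_oracle(self):
        for dose, rate, mu in [(8.0, 277.0, 0.4621), (10.0, 0.5, 0.2), (2.0, 1.0, 1.0)]:
            g = pk.lea_catcheside_G_constant_rate(dose, rate, mu)
            assert g == pytest.approx(g_constant_oracle(dose, rate, mu), abs=1e-8)


class TestGInfinity:
    def test_slow_repair_limit(self):
        assert pk.g_infinity(1.0, 1e9) == pytest.approx(1.0, rel=1e-6)

    def test_y90_with_average_repair_half_life(self):
        g = pk.g_infinity(64.8, 1.5)
        assert g == pytest.approx(0.02262, abs=1e-4)

    def test_bi213_under_appendix_repair_rate(self):
        tau = C.LN2 / 0.42
        g = pk.g_infinity(46.0 / 60.0, tau)
        assert round(g, 1) == 0.7


class TestExtendedLQ:
    PARAMS = CellLineRadioParams("HT29", alpha=0.0842, beta=0.0239)

    def test_zero_dose(self):
        assert pk.survival_extended_lq(self.PARAMS, 1.0, 0.0) == 1.0

    def test_reduces_to_plain_lq_bitwise_at_g_one(self):
        for d in [0.5, 2.0, 8.0, 20.0]:
            expected = math.exp(-(0.0842 * d + 0.0239 * d * d))
            assert pk.survival_extended_lq(self.PARAMS, 1.0, d) == expected

    def test_acute_eight_gray(self):
        sf = pk.survival_extended_lq(self.PARAMS, 1.0, 8.0)
        assert sf == pytest.approx(math.exp(-2.2032), rel=1e-12)
        assert sf == pytest.approx(0.110, abs=5e-4)

    def test_pure_exponential_when_beta_zero(self):
        p = CellLineRadioParams("x", alpha=0.2, beta=0.0)
        assert pk.survival_extended_lq(p, 0.5, 5.0) == pytest.approx(math.exp(-1.0))


class TestCriticalThresholds:
    LAM = C.LN2 / C.Y90_HALF_LIFE_27D_H

    @pytest.mark.parametrize(
        "alpha, t_av, tcrit_ref, rcrit_ref",
        [
            (0.1981, 20.0, 5.883, 0.1749),
            (0.0842, 23.0, 3.095, 0.3578),
            (0.1511, 24.0, 5.538, 0.1911),
        ],
    )
    def test_published_table_to_four_significant_figures(
        self, alpha, t_av, tcrit_ref, rcrit_ref
    ):
        t = pk.critical_time(self.LAM, alpha, 0.792, t_av)
        r = pk.critical_dose_rate(alpha, t_av)
        assert float(f"{t:.4g}") == tcrit_ref
        assert float(f"{r:.4g}") == rcrit_ref

    def test_threshold_case_gives_zero(self):
        alpha, t_av = 0.1, 20.0
        r0 = C.CRIT_THRESHOLD / (alpha * t_av)
        assert pk.critical_time(0.01, alpha, r0, t_av) == pytest.approx(0.0, abs=1e-12)

    def test_never_effective_signalled(self):
        with pytest.raises(NeverEffectiveError):
            pk.critical_time(0.01, 0.01, 0.1, 10.0)

    def test_doubling_alpha_halves_critical_rate(self):
        assert pk.critical_dose_rate(0.2, 20.0) == pytest.approx(
            pk.critical_dose_rate(0.1, 20.0) / 2.0
        )

    @given(
        alpha=st.floats(0.05, 0.5),
        r0=st.floats(0.3, 2.0),
        t_av=st.floats(10.0, 40.0),
        lam=st.floats(1e-3, 0.1),
    )
    def test_rate_at_critical_time_equals_critical_rate(self, alpha, r0, t_av, lam):
        try:
            tcrit_days = pk.critical_time(lam, alpha, r0, t_av)
        except NeverEffectiveError:
            return
        rate = dm.dose_rate_at(r0, lam, tcrit_days * 24.0)
        assert rate == pytest.approx(pk.critical_dose_rate(alpha, t_av), rel=1e-9)


class TestEquieffectiveDose:
    EBRT = CellLineRadioParams("HT29-acute", alpha=0.0842, beta=0.0239)
    Y90 = CellLineRadioParams("HT29-decay", alpha=0.0145, beta=0.0005)

    def test_identity(self):
        d = pk.equieffective_dose(self.EBRT, 1.0, 8.0, self.EBRT, 1.0)
        assert d == pytest.approx(8.0, rel=1e-12)

    def test_linear_branch(self):
        tgt = CellLineRadioParams("lin", alpha=0.1, beta=0.0)
        d = pk.equieffective_dose(self.EBRT, 1.0, 8.0, tgt, 1.0)
        assert d == pytest.approx((0.0842 * 8 + 0.0239 * 64) / 0.1)

    def test_decaying_source_equivalent_of_acute_eight_gray(self):
        # independent root: solve the quadratic with numpy
        effect = 0.0842 * 8 + 0.0239 * 64
        roots = np.roots([0.0005, 0.0145, -effect])
        expected = roots[roots > 0][0]
        d = pk.equieffective_dose(self.EBRT, 1.0, 8.0, self.Y90, 1.0)
        assert d == pytest.approx(expected, rel=1e-10)
        assert 45.0 < d < 60.0  # same order as the reported ~56 Gy


class TestIsotopeTable:
    def test_sorted_descending_and_monotone_in_half_life(self):
        records = pk.isotope_g_table()
        gs = [r.g_infinity for r in records]
        assert gs == sorted(gs, reverse=True)
        halves = [r.half_life_h for r in records]
        assert halves == sorted(halves)

    def test_known_entries(self):
        by_name = {r.name: r.g_infinity for r in pk.isotope_g_table()}
        assert by_name["Bi-213"] == pytest.approx(0.68, abs=0.01)
        assert by_name["Y-90"] == pytest.approx(0.025, abs=0.001)


def test_repair_kinetics_half_life_round_trip():
    rk = RepairKinetics.from_half_life(1.5)
    assert rk.mu_per_h * 1.5 == pytest.approx(C.LN2, rel=1e-12)
    assert rk.half_life_h == pytest.approx(1.5)
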