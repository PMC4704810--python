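"""Closed-form growth/division relations and the fraction-product phase shift."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cyclesens.phenomenology import (
    CycleMetrics,
    FractionPerturbationSeries,
    GrowthLaw,
    coupling_identity,
    mass_doubling_time,
    metrics_from_birth,
    metrics_from_division,
    phase_shift_from_fraction_series,
)

MU100 = math.log(2.0) / 100.0


class TestMassDoublingTime:
    def test_closed_form(self):
        assert mass_doubling_time(MU100) == pytest.approx(100.0, rel=1e-12)
        # ln(2)/0.006931 evaluated independently
        assert mass_doubling_time(0.006931) == pytest.approx(100.006807, rel=1e-6)

    def test_halves_when_mu_doubles(self):
        assert mass_doubling_time(2 * MU100) == pytest.approx(50.0, rel=1e-12)

    def test_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            mass_doubling_time(0.0)
        with pytest.raises(ValueError):
            GrowthLaw(mu=-0.1)


class TestMetricsFromBirth:
    def test_one_doubling_per_cycle_forces_half(self):
        m = metrics_from_birth(V_dau=1.0, T_div=100.0, T_G1=50.0, mu=MU100)
        assert m.V_div == pytest.approx(2.0, rel=1e-12)
        assert m.f == pytest.approx(0.5, rel=1e-12)
        assert m.V_bud == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_direct_exponential_evaluation(self):
        m = metrics_from_birth(V_dau=1.0, T_div=150.0, T_G1=87.12, mu=MU100)
        assert m.V_div == pytest.approx(2 ** 1.5, rel=1e-6)
        assert m.f == pytest.approx(2 ** -1.5, rel=1e-6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(V_dau=-1.0, T_div=100.0, T_G1=50.0, mu=MU100),
            dict(V_dau=1.0, T_div=100.0, T_G1=100.0, mu=MU100),
            dict(V_dau=1.0, T_div=100.0, T_G1=50.0, mu=0.0),
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            metrics_from_birth(**kwargs)


class TestMetricsFromDivision:
    def test_inverts_the_birth_construction(self):
        m = metrics_from_division(V_div=2 ** 1.5, T_div=150.0, mu=MU100)
        assert m.V_dau == pytest.approx(1.0, rel=1e-9)
        # T_G1 from the steady closure V_bud = V_div - V_dau
        assert m.T_G1 == pytest.approx(math.log(2 ** 1.5 - 1) / MU100, rel=1e-9)

    def test_half_fraction_is_infeasible(self):
        with pytest.raises(ValueError, match="[Ff]raction|G1"):
            metrics_from_division(V_div=2.0, T_div=100.0, mu=MU100)

    @given(
        T_div=st.floats(101.0, 400.0),
        mu=st.floats(0.003, 0.02),
        V_div=st.floats(0.5, 200.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_with_metrics_from_birth(self, T_div, mu, V_div):
        try:
            m = metrics_from_division(V_div=V_div, T_div=T_div, mu=mu)
        except ValueError:
            return  # infeasible corner (f >= 0.5); nothing to round-trip
        back = metrics_from_birth(m.V_dau, m.T_div, m.T_G1, mu)
        assert back.V_div == pytest.approx(V_div, rel=1e-12)
        assert back.V_bud == pytest.approx(m.V_bud, rel=1e-12)
        assert back.f == pytest.approx(m.f, rel=1e-12)


@given(
    V_dau=st.floats(0.1, 100.0),
    T_div=st.floats(10.0, 500.0),
    frac=st.floats(0.05, 0.95),
    mu=st.floats(1e-3, 0.05),
)
@settings(max_examples=200, deadline=None)
def test_growth_identities_hold_for_any_construction(V_dau, T_div, frac, mu):
    """V_div = V_dau e^{mu T_div}, V_bud = V_dau e^{mu T_G1}, f = V_dau/V_div."""
    m = metrics_from_birth(V_dau, T_div, frac * T_div, mu)
    assert m.V_div == pytest.approx(m.V_dau * math.exp(mu * m.T_div), rel=1e-12)
    assert m.V_bud == pytest.approx(m.V_dau * math.exp(mu * m.T_G1), rel=1e-12)
    assert m.f == pytest.approx(m.V_dau / m.V_div, rel=1e-12)
    assert m.T_SG2M == pytest.approx(m.T_div - m.T_G1, rel=1e-12)


class TestCouplingIdentity:
    def test_direct_evaluation(self):
        assert coupling_identity(0.3536, 10.0) == pytest.approx(-3.536, rel=1e-12)

    def test_zero_sensitivity_maps_to_zero(self):
        assert coupling_identity(0.4, 0.0) == 0.0

    @given(f=st.floats(0.01, 0.5), c=st.floats(-100.0, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_post_budding_response_at_most_half_of_g1(self, f, c):
        assert abs(coupling_identity(f, c)) <= 0.5 * abs(c) + 1e-12

    def test_domain_error(self):
        with pytest.raises(ValueError):
            coupling_identity(1.5, 1.0)


class TestFractionPhaseShift:
    def test_zero_deviations_give_zero_shift(self):
        s = FractionPerturbationSeries(f0=0.35, delta_f=(0.0, 0.0, 0.0), mu=MU100)
        assert phase_shift_from_fraction_series(s) == 0.0

    def test_single_generation_deviation_closed_form(self):
        # one 10% fraction increase: |shift| = ln(1.1)/mu ~ 13.75 min, and a
        # larger daughter is ahead of schedule, so divisions come earlier
        s = FractionPerturbationSeries(f0=1.0 / 3, delta_f=(1.0 / 30,), mu=MU100)
        shift = phase_shift_from_fraction_series(s)
        assert abs(shift) == pytest.approx(math.log(1.1) / MU100, rel=1e-12)
        assert abs(shift) == pytest.approx(13.75, rel=1e-3)
        assert shift < 0  # advance under the delay-positive convention

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(ValueError):
            FractionPerturbationSeries(f0=0.35, delta_f=(0.7,), mu=MU100)

    @given(
        f0=st.floats(0.1, 0.6),
        dfs=st.lists(st.floats(-0.05, 0.05), min_size=1, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_shift_is_additive_over_generations(self, f0, dfs):
        """The product form makes shifts add across disjoint deviation sets."""
        total = phase_shift_from_fraction_series(
            FractionPerturbationSeries(f0, tuple(dfs), MU100)
        )
        parts = sum(
            phase_shift_from_fraction_series(
                FractionPerturbationSeries(f0, (df,), MU100)
            )
            for df in dfs
        )
        assert total == pytest.approx(parts, abs=1e-9)


def test_observable_names_are_stable():
    assert CycleMetrics.OBSERVABLES == (
        "T_div", "T_G1", "T_SG2M", "V_div", "V_bud", "V_dau", "f",
    )
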