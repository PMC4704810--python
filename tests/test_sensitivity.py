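"""Static and dynamic parametric sensitivities on the minimal model."""

import numpy as np
import pytest

from cyclesens.sensitivity import (
    DynamicSensitivityCurve,
    SensitivityUndefinedError,
    _sequence_is_nonmonotonic,
    dynamic_sensitivity_all,
    sign_concordance,
    static_sensitivity,
    static_sensitivity_table,
    superpose,
)


@pytest.fixture(scope="module")
def static_table(pfeuty):
    return static_sensitivity_table(pfeuty)


class TestStaticSensitivity:
    def test_richardson_step_refinement(self, pfeuty, pfeuty_steady):
        """Halving the log-step changes C by under 0.5% (central difference is O(d^2))."""
        _, start = pfeuty_steady
        coarse = {s.observable: s.value
                  for s in static_sensitivity(pfeuty, "d_y", delta=0.02, start=start)}
        fine = {s.observable: s.value
                for s in static_sensitivity(pfeuty, "d_y", delta=0.01, start=start)}
        for q in ("T_div", "T_G1", "V_div"):
            assert fine[q] == pytest.approx(coarse[q], rel=5e-3)

    def test_secant_over_larger_step_agrees(self, pfeuty, pfeuty_steady):
        """A 10x larger secant shows only the expected O(delta^2) discrepancy."""
        _, start = pfeuty_steady
        small = {s.observable: s.value
                 for s in static_sensitivity(pfeuty, "K_y", delta=0.01, start=start)}
        big = {s.observable: s.value
               for s in static_sensitivity(pfeuty, "K_y", delta=0.1, start=start)}
        assert big["T_div"] == pytest.approx(small["T_div"], rel=0.05)

    def test_cln3_analogue_shrinks_cells(self, static_table):
        wide = static_table.pivot_table(index="parameter", columns="observable", values="C")
        assert wide.loc["s_x2", "V_div"] < 0
        assert wide.loc["s_x2", "V_dau"] < 0

    def test_growth_rate_speeds_cycle_and_grows_daughters(self, static_table):
        wide = static_table.pivot_table(index="parameter", columns="observable", values="C")
        assert wide.loc["mu", "T_div"] < 0
        assert wide.loc["mu", "V_dau"] > 0

    def test_unknown_parameter_rejected(self, pfeuty):
        with pytest.raises(KeyError):
            static_sensitivity(pfeuty, "nope")

    def test_arresting_perturbation_reports_undefined(self, pfeuty, pfeuty_steady):
        _, start = pfeuty_steady
        broken = pfeuty.with_params(s_y=pfeuty.params["s_y"] * 0.02)
        with pytest.raises(SensitivityUndefinedError):
            static_sensitivity(broken, "s_y", start=start)


class TestSensitivityTable:
    def test_one_row_per_parameter_observable_pair(self, static_table, pfeuty):
        assert len(static_table) == pfeuty.n_params * 7
        assert set(static_table["parameter"]) == set(pfeuty.params)

    def test_phase_duration_coupling_slope(self, static_table, pfeuty_steady):
        """C^{T_SG2M} = -f * C^{T_G1} for every kinetic parameter (fixed mu)."""
        metrics, _ = pfeuty_steady
        wide = static_table.pivot_table(index="parameter", columns="observable", values="C")
        wide = wide.drop(index="mu")
        mask = wide["T_G1"].abs() > 1e-3
        ratio = -wide.loc[mask, "T_SG2M"] / wide.loc[mask, "T_G1"]
        assert np.allclose(ratio, metrics.f, rtol=0.05)

    def test_chain_rule_from_division_variables(self, static_table, pfeuty_steady, pfeuty):
        """(C^{T_div}, C^{V_div}) determine C^{V_dau} and C^{T_G1} at fixed mu."""
        metrics, _ = pfeuty_steady
        mu = pfeuty.mu
        wide = static_table.pivot_table(index="parameter", columns="observable", values="C")
        for k in wide.index:
            if k == "mu":
                continue  # the chain rule below holds at fixed growth rate only
            c_tdiv, c_vdiv = wide.loc[k, "T_div"], wide.loc[k, "V_div"]
            # V_dau = V_div e^{-mu T_div}
            c_vdau = (c_vdiv - metrics.V_div * mu * c_tdiv) * np.exp(-mu * metrics.T_div)
            # T_G1 = (1/mu) ln((V_div - V_dau)/V_dau)
            dd = (c_vdiv - c_vdau) / (metrics.V_div - metrics.V_dau) - c_vdau / metrics.V_dau
            c_tg1 = dd / mu
            scale = max(abs(wide.loc[k, "V_dau"]), 1e-3)
            assert abs(c_vdau - wide.loc[k, "V_dau"]) <= 0.01 * scale + 1e-4
            scale = max(abs(wide.loc[k, "T_G1"]), 1e-2)
            assert abs(c_tg1 - wide.loc[k, "T_G1"]) <= 0.01 * scale + 1e-2


class TestSignConcordance:
    def test_single_same_sign_row(self):
        import pandas as pd

        tab = pd.DataFrame(
            [
                {"parameter": "k", "observable": "V_dau", "C": 1.0},
                {"parameter": "k", "observable": "T_G1", "C": 1.0},
            ]
        )
        assert sign_concordance(tab) == (1.0, 0.0)

    def test_proportions_sum_to_one(self, static_table):
        same, opp = sign_concordance(static_table, floor=1e-3)
        assert same + opp == pytest.approx(1.0)

    def test_opposite_sign_majority(self, static_table):
        same, opp = sign_concordance(static_table, floor=1e-3)
        assert opp > same


@pytest.fixture(scope="module")
def curves(pfeuty, pfeuty_steady):
    metrics, start = pfeuty_steady
    grid = np.linspace(0.0, metrics.T_div, 8, endpoint=False)
    return dynamic_sensitivity_all(
        pfeuty, "d_y", grid, n_gens=6, start=start, steady=metrics
    )


class TestDynamicSensitivity:
    def test_late_generations_approach_static_limit(self, curves):
        c = curves["T_div"]
        scale = max(abs(c.C), np.nanmax(np.abs(c.S)))
        assert np.nanmax(np.abs(c.S[-1] - c.C)) <= 0.02 * scale

    def test_supremum_deviation_decreases_with_generation(self, curves):
        c = curves["T_G1"]
        sup = [np.nanmax(np.abs(c.S[i] - c.C)) for i in range(c.n_gens)]
        assert sup[-1] < sup[0]

    def test_perturbations_after_an_event_cannot_change_it(self, curves, pfeuty_steady):
        """T_G1 of generation 1 is fixed once budding happened, so late-cycle
        steps leave it untouched."""
        metrics, _ = pfeuty_steady
        c = curves["T_G1"]
        late = c.t_grid > metrics.T_G1 + 1.0
        assert np.allclose(c.S[0, late], 0.0, atol=1e-3 * max(1.0, abs(c.C)))


class TestNonmonotonicityClassifier:
    def test_monotone_sequences_are_not_flagged(self):
        assert not _sequence_is_nonmonotonic(np.array([0.0, 1.0, 2.0, 3.0]), 1e-6)
        assert not _sequence_is_nonmonotonic(np.array([3.0, 1.0, 0.5, 0.2]), 1e-6)

    def test_alternating_sequence_is_flagged(self):
        assert _sequence_is_nonmonotonic(np.array([0.0, 1.0, -1.0, 1.0]), 1e-6)

    def test_ripple_below_tolerance_is_ignored(self):
        seq = np.array([0.0, 1.0, 0.9999, 2.0])
        assert not _sequence_is_nonmonotonic(seq, eps=1e-2)


class TestSuperposition:
    def _curve(self, parameter, grid, values):
        S = np.tile(values, (3, 1)).astype(float)
        return DynamicSensitivityCurve(
            parameter=parameter, observable="V_dau", t_grid=grid,
            S=S, Z=np.zeros_like(S), C=float(values[-1]),
        )

    def test_weighted_sum_of_curves(self):
        grid = np.linspace(0.0, 100.0, 5)
        a = self._curve("a", grid, np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        b = self._curve("b", grid, np.array([10.0, 10.0, 10.0, 10.0, 10.0]))
        out = superpose([a, b], [("a", 0.1), ("b", 0.2)], t=50.0)
        assert out == pytest.approx([0.3 + 2.0] * 3)

    def test_zero_deltas_give_zero_response(self):
        grid = np.linspace(0.0, 100.0, 5)
        a = self._curve("a", grid, np.arange(5.0))
        assert np.allclose(superpose([a], [("a", 0.0)], t=10.0), 0.0)

    def test_mismatched_grids_rejected(self):
        a = self._curve("a", np.linspace(0, 100, 5), np.arange(5.0))
        b = self._curve("b", np.linspace(0, 90, 5), np.arange(5.0))
        with pytest.raises(ValueError):
            superpose([a, b], [("a", 0.1), ("b", 0.1)], t=10.0)
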