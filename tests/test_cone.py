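"""Attainable-cone machinery, checked against a brute-force angular oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyclesens.attainable_region import (
    AttainableCone,
    ResponseVector,
    build_cone,
    contains,
    weight_families,
)


def angle(v: ResponseVector) -> float:
    return math.atan2(v.dV_dau, v.dT_G1)


TWO_PI = 2 * math.pi


def oracle_contains(generators: list[ResponseVector], v: ResponseVector) -> bool:
    """Angular-sweep membership oracle for 2-D cones.

    A 2-D cone is the union of the arcs spanned by generator pairs; a
    convex combination of two generators sweeps its arc monotonically, so
    each pair's arc is identified by the direction of the midpoint sum and
    the probe is tested against every arc (plus the generator rays).
    """
    if v.norm == 0:
        return True
    pa = angle(v)
    tol = 1e-9
    angs = [angle(g) for g in generators]
    for a in angs:
        if abs((pa - a + math.pi) % TWO_PI - math.pi) <= tol:
            return True
    for i in range(len(generators)):
        for j in range(i + 1, len(generators)):
            a, b = angs[i], angs[j]
            gi, gj = generators[i].as_array(), generators[j].as_array()
            mid_v = gi / np.linalg.norm(gi) + gj / np.linalg.norm(gj)
            if np.linalg.norm(mid_v) < 1e-12:
                # antiparallel pair: spans the full line; both half-planes
                # are reachable by leaning on either side, skip to rays
                continue
            mid = math.atan2(mid_v[1], mid_v[0])
            span = (b - a) % TWO_PI
            if (mid - a) % TWO_PI > span:
                a, b = b, a
                span = (b - a) % TWO_PI
            if (pa - a) % TWO_PI <= span + tol:
                return True
    return False


vec = st.builds(
    ResponseVector,
    st.floats(-10.0, 10.0).filter(lambda x: abs(x) > 1e-3),
    st.floats(-10.0, 10.0).filter(lambda x: abs(x) > 1e-3),
)


class TestMembership:
    def test_single_generator_is_a_ray(self):
        g = ResponseVector(-1.0, 0.5)
        cone = build_cone([g])
        inside, w = contains(cone, ResponseVector(-2.0, 1.0))
        assert inside and w[0] == pytest.approx(2.0)
        assert contains(cone, ResponseVector(1.0, 0.5))[0] is False

    def test_generators_are_inside_with_unit_weight(self):
        gens = [ResponseVector(-1.0, 0.3), ResponseVector(1.0, 0.2)]
        cone = build_cone(gens)
        for i, g in enumerate(gens):
            inside, w = contains(cone, g)
            assert inside
            recon = cone.matrix() @ w
            assert np.allclose(recon, g.as_array(), atol=1e-9)

    def test_negation_of_interior_vector_is_outside_pointed_cone(self):
        cone = build_cone([ResponseVector(-1.0, 0.1), ResponseVector(-1.0, -0.1)])
        interior = ResponseVector(-1.0, 0.0)
        assert contains(cone, interior)[0]
        assert not contains(cone, ResponseVector(1.0, 0.0))[0]

    @given(gens=st.lists(vec, min_size=1, max_size=4), probe=vec)
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_angular_sweep_oracle(self, gens, probe):
        cone = build_cone(gens)
        inside, w = contains(cone, probe)
        # skip hairline cases where both verdicts are legitimately fragile
        ang_p = angle(probe)
        margin = min(abs((angle(g) - ang_p + math.pi) % (2 * math.pi) - math.pi)
                     for g in gens)
        if margin < 1e-3:
            return
        assert inside == oracle_contains(gens, probe)
        if inside:
            recon = cone.matrix() @ w
            assert np.allclose(recon, probe.as_array(), atol=1e-7 * max(1.0, probe.norm))

    def test_witness_reproduces_target_to_solver_precision(self):
        gens = [ResponseVector(-2.2, -0.7), ResponseVector(3.0, -1.4),
                ResponseVector(-31.0, 4.4)]
        cone = build_cone(gens)
        probe = ResponseVector(-10.0, 1.0)
        inside, w = contains(cone, probe)
        assert inside
        recon = cone.matrix() @ w
        assert np.allclose(recon, probe.as_array(), atol=1e-9 * probe.norm)


class TestConeGeometry:
    def test_interior_generator_does_not_widen_the_wedge(self):
        outer = [ResponseVector(-1.0, 1.0), ResponseVector(1.0, 1.0)]
        inner = ResponseVector(0.0, 1.0)
        cone = build_cone(outer + [inner])
        rays = cone.extreme_rays()
        assert len(rays) == 2
        ray_angles = sorted(angle(r) for r in rays)
        assert ray_angles == pytest.approx([math.pi / 4, 3 * math.pi / 4])

    def test_degenerate_generator_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cone = build_cone(
                [ResponseVector(-1.0, 0.3), ResponseVector(0.0, 0.0)],
                drop_tol=1e-12,
            )
        assert len(cone.generators) == 1

    def test_opposing_generators_span_the_half_plane_boundary(self):
        cone = build_cone([ResponseVector(1.0, 0.0), ResponseVector(-1.0, 0.0)])
        assert contains(cone, ResponseVector(0.5, 0.0))[0]
        assert not contains(cone, ResponseVector(0.0, 1.0))[0]


class TestWeightFamilies:
    GENS = [ResponseVector(-2.0, -1.0), ResponseVector(3.0, -1.0),
            ResponseVector(-4.0, 2.0)]
    NAMES = ["cln3", "clbS", "net1"]

    def cone(self):
        return build_cone(self.GENS, self.NAMES)

    def test_two_free_channels_give_unique_solution(self):
        cone = self.cone()
        target = ResponseVector(-0.5, -1.5)  # 1*cln3 + 0.5*clbS
        w = weight_families(cone, target, fixed=[("net1", 0.0)])
        recon = cone.matrix() @ np.array([w[n] for n in self.NAMES])
        assert np.allclose(recon, target.as_array(), atol=1e-9)

    def test_target_scaling_scales_weights(self):
        cone = self.cone()
        t1 = ResponseVector(-0.5, -1.5)
        t2 = ResponseVector(-1.0, -3.0)
        w1 = weight_families(cone, t1, fixed=[("net1", 0.0)])
        w2 = weight_families(cone, t2, fixed=[("net1", 0.0)])
        for n in ("cln3", "clbS"):
            assert w2[n] == pytest.approx(2 * w1[n], rel=1e-9)

    def test_families_share_endpoint_as_fixed_weight_varies(self):
        cone = self.cone()
        target = ResponseVector(-0.5, -1.5)
        A = cone.matrix()
        for net1_w in (0.0, 0.1, 0.2):
            w = weight_families(cone, target, fixed=[("net1", net1_w)])
            recon = A @ np.array([w[n] for n in self.NAMES])
            assert np.allclose(recon, target.as_array(), atol=1e-9)

    def test_infeasible_balance_names_the_channel(self):
        cone = self.cone()
        # a target deep outside the (cln3, clbS) wedge needs a negative weight
        target = ResponseVector(0.0, 5.0)
        with pytest.raises(ValueError, match="negative weight"):
            weight_families(cone, target, fixed=[("net1", 0.0)])


@pytest.fixture(scope="module")
def weighted_setup():
    import numpy as np
    from cyclesens.models import build_model
    from cyclesens.models.spec import RegulationChannel
    from cyclesens.sensitivity import dynamic_sensitivity_all
    from cyclesens.simulate import find_steady_cycle

    model = build_model("pfeuty")
    steady, start = find_steady_cycle(model)
    grid = np.linspace(0.0, steady.T_div, 6, endpoint=False)
    channels = [
        RegulationChannel("g1_arm", ("s_x2",), +1),
        RegulationChannel("mitotic_arm", ("d_y",), -1),
    ]
    curves = {
        k: dynamic_sensitivity_all(model, k, grid, n_gens=1,
                                   start=start, steady=steady)["V_dau"]
        for k in ("s_x2", "d_y")
    }
    return model, channels, grid, curves, (start, steady)


class TestDynamicResponseOfWeights:
    """Weighted superposition of channel dynamic responses (generic mode)."""

    def test_zero_weights_give_flat_zero_response(self, weighted_setup):
        import numpy as np
        from cyclesens.attainable_region import dynamic_response_of_weights

        model, channels, grid, curves, (start, steady) = weighted_setup
        out = dynamic_response_of_weights(
            model, channels, {"g1_arm": 0.0, "mitotic_arm": 0.0}, grid,
            start=start, steady=steady, curves=curves,
        )
        assert np.allclose(out, 0.0)

    def test_weighted_sum_matches_manual_superposition(self, weighted_setup):
        import numpy as np
        from cyclesens.attainable_region import dynamic_response_of_weights

        model, channels, grid, curves, (start, steady) = weighted_setup
        w = {"g1_arm": 0.4, "mitotic_arm": 1.5}
        out = dynamic_response_of_weights(
            model, channels, w, grid, start=start, steady=steady, curves=curves,
        )
        manual = 0.4 * curves["s_x2"].S[0] + 1.5 * (-1) * curves["d_y"].S[0]
        assert np.allclose(out, manual, atol=1e-12)

    def test_grid_mismatch_rejected(self, weighted_setup):
        import numpy as np
        from cyclesens.attainable_region import dynamic_response_of_weights

        model, channels, grid, curves, (start, steady) = weighted_setup
        with pytest.raises(ValueError, match="grid"):
            dynamic_response_of_weights(
                model, channels, {"g1_arm": 1.0}, grid[:-1],
                start=start, steady=steady, curves=curves,
            )
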