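"""Attainable-region analysis of coregulated signalling channels.

A signalling channel moves a set of model parameters together (with a fixed
sign for an increasing signal).  Its effect on the steady cycle is a
direction in (ΔT_G1, ΔV_dau) space — the sum of the member parameters'
static sensitivities, oriented by the channel sign.  The attainable region
for a signal that co-activates several channels with nonnegative strengths
is the convex cone spanned by the channel vectors: only (ΔT_G1, ΔV_dau)
combinations inside the cone are reachable, and any interior point is
reachable by infinitely many weight assignments that differ in their
*dynamic* (transient) responses while agreeing at steady state.

The empirical glucose response direction used as a reference is
(ΔT_G1, ΔV_dau) ∝ (−1, +0.27): more glucose shortens G1 and enlarges
daughters, with 0.27 fL of daughter volume gained per minute of G1 lost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .models.spec import ModelSpec, RegulationChannel
from .sensitivity import (
    DynamicSensitivityCurve,
    dynamic_sensitivity_all,
    static_sensitivity,
)
from .simulate import find_steady_cycle

__all__ = [
    "ResponseVector",
    "AttainableCone",
    "GLUCOSE_REFERENCE_DIRECTION",
    "channel_vector",
    "build_cone",
    "contains",
    "weight_families",
    "dynamic_response_of_weights",
]

#: empirical direction of the glucose response in (dT_G1, dV_dau):
#: G1 shortens while daughters grow by 0.27 volume units per minute of G1.
GLUCOSE_REFERENCE_DIRECTION = (-1.0, 0.27)

#: relative residual below which a nonnegative decomposition counts as exact.
_MEMBERSHIP_RTOL = 1e-9


@dataclass(frozen=True)
class ResponseVector:
    """Direction of steady-cycle response: (ΔT_G1 in min, ΔV_dau in volume)."""

    dT_G1: float
    dV_dau: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dT_G1, self.dV_dau])

    @property
    def norm(self) -> float:
        return math.hypot(self.dT_G1, self.dV_dau)


@dataclass
class AttainableCone:
    """Positive-combination cone of channel response vectors."""

    generators: list[ResponseVector]
    channel_names: list[str] = field(default_factory=list)

    def matrix(self) -> np.ndarray:
        """2 × n matrix of generator columns."""
        return np.column_stack([g.as_array() for g in self.generators])

    def extreme_rays(self) -> list[ResponseVector]:
        """Boundary generators of a pointed 2-D cone.

        When the generators span at most a half-plane the cone is the wedge
        between the two angular extremes; otherwise every direction is
        attainable and the notion of boundary rays is empty.
        """
        angles = np.array(
            [math.atan2(g.dV_dau, g.dT_G1) for g in self.generators]
        )
        if len(angles) == 1:
            return [self.generators[0]]
        # test every generator direction as a potential half-plane edge
        for i, a in enumerate(angles):
            rel = (angles - a) % (2 * math.pi)
            if np.all(rel <= math.pi + 1e-12):
                j = int(np.argmax(rel))
                return [self.generators[i], self.generators[j]]
        return []

    @property
    def is_pointed(self) -> bool:
        return len(self.generators) == 1 or len(self.extreme_rays()) == 2


def channel_vector(
    model: ModelSpec,
    channel: RegulationChannel,
    sensitivities: Mapping[str, Mapping[str, float]] | None = None,
    start=None,
) -> ResponseVector:
    """Response direction of one channel to an increasing signal.

    Coupled parameters share one multiplier, so the channel direction is
    sign · Σ_k (C_k^{T_G1}, C_k^{V_dau}) over its member parameters.
    ``sensitivities`` may supply precomputed per-parameter {observable: C}
    maps; otherwise they are computed here.
    """
    channel.validate_against(model)
    tot = np.zeros(2)
    for k in channel.parameters:
        if sensitivities is not None and k in sensitivities:
            c = sensitivities[k]
            pair = (c["T_G1"], c["V_dau"])
        else:
            res = {s.observable: s.value for s in
                   static_sensitivity(model, k, ("T_G1", "V_dau"), start=start)}
            pair = (res["T_G1"], res["V_dau"])
        if not all(np.isfinite(pair)):
            raise ValueError(f"undefined sensitivity for channel parameter {k!r}")
        tot += pair
    tot *= channel.sign
    return ResponseVector(float(tot[0]), float(tot[1]))


def build_cone(
    vectors: Sequence[ResponseVector],
    names: Sequence[str] | None = None,
    drop_tol: float = 0.0,
) -> AttainableCone:
    """Cone of all nonnegative combinations of the given vectors.

    Near-zero vectors (norm ≤ drop_tol relative to the largest) are
    degenerate generators and are dropped with a warning.
    """
    if not vectors:
        raise ValueError("need at least one response vector")
    names = list(names) if names is not None else [f"channel_{i}" for i in range(len(vectors))]
    scale = max(v.norm for v in vectors)
    keep_v, keep_n = [], []
    for v, n in zip(vectors, names):
        if scale == 0 or v.norm <= drop_tol * scale:
            warnings.warn(f"dropping degenerate (all-zero) channel generator {n!r}")
            continue
        keep_v.append(v)
        keep_n.append(n)
    if not keep_v:
        raise ValueError("all generators are degenerate")
    return AttainableCone(keep_v, keep_n)


def contains(
    cone: AttainableCone, v: ResponseVector, rtol: float = 1e-7
) -> tuple[bool, np.ndarray | None]:
    """Membership of a direction in the cone, up to positive scaling.

    Returns (inside, weights):  when inside, ``weights`` are nonnegative
    channel weights whose combination reproduces ``v`` exactly (to the
    solver's residual, ~1e-12 relative).
    """
    A = cone.matrix()
    b = v.as_array()
    nb = np.linalg.norm(b)
    if nb == 0:
        return True, np.zeros(A.shape[1])
    w, resid = nnls(A, b)
    if resid <= rtol * nb:
        return True, w
    return False, None


def weight_families(
    cone: AttainableCone,
    target: ResponseVector,
    fixed: Sequence[tuple[str, float]] = (),
) -> dict[str, float]:
    """Nonnegative channel weights reaching ``target`` with some weights fixed.

    The two steady-state equations (ΔT_G1, ΔV_dau) determine the remaining
    weights once the fixed ones are chosen; with two free channels the
    solution is unique.  Raises an infeasibility error naming the violated
    channel when the balancing weights would have to be negative.
    """
    name_to_idx = {n: i for i, n in enumerate(cone.channel_names)}
    for n, w in fixed:
        if n not in name_to_idx:
            raise KeyError(f"unknown channel {n!r}")
        if w < 0:
            raise ValueError(f"fixed weight for {n!r} must be nonnegative")
    fixed_map = dict(fixed)
    free = [n for n in cone.channel_names if n not in fixed_map]
    A = cone.matrix()
    b = target.as_array() - sum(
        w * A[:, name_to_idx[n]] for n, w in fixed_map.items()
    )
    if not free:
        if np.linalg.norm(b) > 1e-9 * max(1.0, target.norm):
            raise ValueError("fixed weights do not reach the target")
        return dict(fixed_map)
    Af = A[:, [name_to_idx[n] for n in free]]
    if len(free) == 2:
        try:
            w = np.linalg.solve(Af, b)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"free channels are collinear: {err}") from err
    else:
        w, *_ = np.linalg.lstsq(Af, b, rcond=None)
        if np.linalg.norm(Af @ w - b) > 1e-9 * max(1.0, target.norm):
            raise ValueError("target not reachable with the given fixed weights")
    bad = [n for n, wi in zip(free, w) if wi < -1e-12]
    if bad:
        raise ValueError(
            f"infeasible weight family: channel(s) {bad} would need negative weight"
        )
    out = dict(fixed_map)
    out.update({n: float(max(wi, 0.0)) for n, wi in zip(free, w)})
    return out


def dynamic_response_of_weights(
    model: ModelSpec,
    channels: Sequence[RegulationChannel],
    weights: Mapping[str, float],
    t_grid: np.ndarray,
    observable: str = "V_dau",
    generation: int = 1,
    delta: float = 0.01,
    start=None,
    steady=None,
    curves: Mapping[str, DynamicSensitivityCurve] | None = None,
) -> np.ndarray:
    """First-generation dynamic response of the weighted channel combination.

    Superposes the per-parameter dynamic sensitivity curves of
    ``observable`` in the given generation:
    S_combined(t) = Σ_ch w_ch · sign_ch · Σ_{k ∈ ch} S_k(t).
    ``curves`` may supply precomputed per-parameter curves on ``t_grid``.
    """
    if start is None or steady is None:
        steady, start = find_steady_cycle(model)
    total = np.zeros(np.asarray(t_grid).size)
    for ch in channels:
        w = weights.get(ch.name, 0.0)
        if w == 0.0:
            continue
        for k in ch.parameters:
            if curves is not None and k in curves:
                c = curves[k]
                if c.t_grid.size != np.asarray(t_grid).size or not np.allclose(c.t_grid, t_grid):
                    raise ValueError(f"curve grid mismatch for parameter {k!r}")
            else:
                c = dynamic_sensitivity_all(
                    model, k, np.asarray(t_grid, float), n_gens=generation,
                    delta=delta, start=start, steady=steady,
                )[observable]
            total += w * ch.sign * c.S[generation - 1]
    return total
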