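"""Synthetic lineage event streams with exact growth phenomenology.

The generator emulates the birth → budding → division event structure of a
daughter lineage growing exponentially at rate ``mu``, without any ODE
model: each generation's events are placed in closed form, so the
exponential-growth identities hold exactly and downstream consumers
(metric extraction, phase-shift formulas, table writers) can be tested
against known ground truth.

A schedule of per-generation deviations Δf_i of the donated volume fraction
is realised through the sizer mechanics of the phenomenological model:
budding stays at a fixed volume, and the division of generation i is moved
so the fraction donated to the next daughter is f0 + Δf_i.  The cumulative
division-time shift of such a stream equals the closed-form phase shift
−(1/mu)·ln ∏ (f0 + Δf_i)/f0 exactly (delay-positive convention).

Noise, when requested, is a multiplicative log-normal jitter applied to
the *recorded* volumes of each generation (one draw per generation, event
timings exact, nothing propagated to later generations) — measurement-like
noise that lets estimator recovery be tested, not a model of biological
variability.  Within a generation the jitter cancels out of the growth
identities, so noisy streams still satisfy them exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .simulate import EventRecord, LineageTrajectory

__all__ = ["LineageEventStream", "generate_lineage", "unbudded_fraction"]


@dataclass
class LineageEventStream(LineageTrajectory):
    """A synthetic lineage trajectory plus the parameters that generated it."""

    params: dict = field(default_factory=dict)


def generate_lineage(
    mu: float,
    T_div: float,
    T_G1: float,
    n_gens: int,
    delta_f: tuple[float, ...] = (),
    noise_sd: float = 0.0,
    seed: int | None = None,
    V_birth: float = 1.0,
) -> LineageEventStream:
    """Generate a synthetic daughter-lineage event stream.

    The baseline stream repeats (T_div, T_G1) exactly in every generation.
    ``delta_f[i-1]`` shifts generation i's division (and generation i+1's
    budding) so the donated fraction becomes f0 + Δf_i, where
    f0 = e^{−mu·T_div} is the steady daughter fraction implied by T_div.
    Deterministic given ``seed``.
    """
    if not (mu > 0 and T_div > 0 and 0 < T_G1 < T_div and n_gens >= 1):
        raise ValueError("need mu, T_div > 0, 0 < T_G1 < T_div and n_gens >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    f0 = math.exp(-mu * T_div)
    fractions = []
    for i in range(n_gens):
        df = delta_f[i] if i < len(delta_f) else 0.0
        g = f0 + df
        if not 0.0 < g < 1.0:
            raise ValueError(f"infeasible delta_f[{i}]: fraction {g} outside (0, 1)")
        fractions.append(g)

    rng = np.random.default_rng(seed)
    stream = LineageEventStream(
        mu=mu,
        params={
            "mu": mu, "T_div": T_div, "T_G1": T_G1, "n_gens": n_gens,
            "delta_f": tuple(delta_f), "noise_sd": noise_sd, "seed": seed,
        },
    )
    inv_mu = 1.0 / mu
    T_SG2M = T_div - T_G1
    t = 0.0
    V_b = V_birth
    g_prev = f0
    for i in range(1, n_gens + 1):
        jitter = math.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
        g = fractions[i - 1]
        # sizer mechanics: the previous generation's extra donation advances
        # this budding; this generation's donation target moves its division.
        tg1 = T_G1 + inv_mu * (
            math.log((1 - g_prev) / g_prev) - math.log((1 - f0) / f0)
        )
        tsg2m = T_SG2M + inv_mu * (math.log(1 - f0) - math.log(1 - g))
        if not 0 < tg1 < tg1 + tsg2m:
            raise ValueError(f"delta_f schedule makes generation {i} infeasible")
        tdiv = tg1 + tsg2m
        V_bud = V_b * math.exp(mu * tg1)
        V_div = V_b * math.exp(mu * tdiv)
        stream.events.append(EventRecord(i, "birth", t, V_b * jitter))
        stream.events.append(EventRecord(i, "bud", t + tg1, V_bud * jitter))
        stream.events.append(EventRecord(i, "division", t + tdiv, V_div * jitter))
        t += tdiv
        V_b = V_div - V_bud
        g_prev = g
    return stream


def unbudded_fraction(T_G1: float, T_div: float) -> float:
    """Population fraction of unbudded (G1) cells — simple proportional proxy.

    F_G1 = T_G1 / T_div.  This is the first-order proxy linking the
    unbudded fraction of an asynchronous population to the G1 duration; an
    age-structured population model would weight young cells more strongly
    but preserves the monotone proportionality this proxy captures.
    """
    if not (T_div > 0 and 0 <= T_G1 <= T_div):
        raise ValueError("need 0 <= T_G1 <= T_div with T_div > 0")
    return T_G1 / T_div
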