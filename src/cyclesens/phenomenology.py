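"""Closed-form relations among macroscopic cell-cycle observables.

A budding-yeast daughter cell grows exponentially at rate ``mu`` (1/min),
buds at the G1/S transition, directs all post-budding growth to the bud, and
donates the whole bud to the daughter at division.  Under these assumptions
the per-generation observables

    T_div   cycle duration (birth to division), min
    T_G1    pre-budding (G1) duration, min
    T_SG2M  post-budding duration, min
    V_dau   volume at birth
    V_bud   volume at budding
    V_div   volume at division
    f       daughter fraction V_dau / V_div

are linked by ``V_div = V_dau e^{mu T_div}``, ``V_bud = V_dau e^{mu T_G1}``
and ``f = V_dau / V_div``.  The mass doubling time ln(2)/mu is generally
different from T_div: the division period is set by the underlying cell-cycle
machinery, not by growth alone.

All times are minutes; volumes are arbitrary (fL-like) units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GrowthLaw",
    "CycleMetrics",
    "FractionPerturbationSeries",
    "mass_doubling_time",
    "metrics_from_birth",
    "metrics_from_division",
    "coupling_identity",
    "phase_shift_from_fraction_series",
]

#: truncation rule for the per-generation products/sums: stop once the
#: relative per-generation increment falls below this, or after MAX_GENS.
REL_INCREMENT_TOL = 1e-9
MAX_GENS = 20


@dataclass(frozen=True)
class GrowthLaw:
    """Exponential growth at rate ``mu`` (1/min)."""

    mu: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"growth rate mu must be positive, got {self.mu}")

    @property
    def mass_doubling_time(self) -> float:
        return math.log(2.0) / self.mu


@dataclass(frozen=True)
class CycleMetrics:
    """Macroscopic observables of one daughter-cell cycle."""

    T_div: float
    T_G1: float
    T_SG2M: float
    V_div: float
    V_bud: float
    V_dau: float
    f: float
    mu: float

    def as_dict(self) -> dict[str, float]:
        return {
            "T_div": self.T_div,
            "T_G1": self.T_G1,
            "T_SG2M": self.T_SG2M,
            "V_div": self.V_div,
            "V_bud": self.V_bud,
            "V_dau": self.V_dau,
            "f": self.f,
        }

    #: ordered observable names, as used by the sensitivity engine.
    OBSERVABLES = ("T_div", "T_G1", "T_SG2M", "V_div", "V_bud", "V_dau", "f")


def mass_doubling_time(mu: float) -> float:
    """Mass doubling time ln(2)/mu, minutes."""
    if not mu > 0:
        raise ValueError(f"mu must be positive, got {mu}")
    return math.log(2.0) / mu


def metrics_from_birth(V_dau: float, T_div: float, T_G1: float, mu: float) -> CycleMetrics:
    """Populate a full :class:`CycleMetrics` from birth size and phase durations.

    Applies the exponential-growth identities directly:
    ``V_div = V_dau e^{mu T_div}``, ``V_bud = V_dau e^{mu T_G1}``,
    ``f = V_dau / V_div``.
    """
    if not (V_dau > 0 and T_div > 0 and T_G1 > 0 and mu > 0):
        raise ValueError("V_dau, T_div, T_G1 and mu must all be positive")
    if T_G1 >= T_div:
        raise ValueError(f"T_G1 ({T_G1}) must be smaller than T_div ({T_div})")
    V_div = V_dau * math.exp(mu * T_div)
    V_bud = V_dau * math.exp(mu * T_G1)
    return CycleMetrics(
        T_div=T_div,
        T_G1=T_G1,
        T_SG2M=T_div - T_G1,
        V_div=V_div,
        V_bud=V_bud,
        V_dau=V_dau,
        f=V_dau / V_div,
        mu=mu,
    )


def metrics_from_division(V_div: float, T_div: float, mu: float) -> CycleMetrics:
    """Recover the full steady-cycle metrics from (V_div, T_div) alone.

    At a steady daughter cycle the bud is the next daughter
    (``V_bud = V_div − V_dau``), which closes the system:
    ``V_dau = V_div e^{−mu T_div}`` and
    ``T_G1 = −(1/mu) ln(V_dau / (V_div − V_dau))``.

    Raises an infeasibility error when the implied daughter fraction is
    ≥ 0.5, which would require a negative G1 duration.
    """
    if not (V_div > 0 and T_div > 0 and mu > 0):
        raise ValueError("V_div, T_div and mu must all be positive")
    V_dau = V_div * math.exp(-mu * T_div)
    if V_dau >= V_div - V_dau:
        raise ValueError(
            "infeasible steady cycle: implied daughter fraction "
            f"f = {V_dau / V_div:.6g} >= 0.5 (negative G1 duration)"
        )
    T_G1 = -math.log(V_dau / (V_div - V_dau)) / mu
    return metrics_from_birth(V_dau=V_dau, T_div=T_div, T_G1=T_G1, mu=mu)


def coupling_identity(f: float, C_TG1: float) -> float:
    """Steady-state coupling of phase-duration sensitivities.

    Any parameter change that alters the G1 duration must alter the
    post-budding duration in the opposite direction, in the fixed ratio
    ``C^{T_SG2M} = −f · C^{T_G1}``.  Since f ≤ 0.5 at a steady daughter
    cycle, |C^{T_SG2M}| ≤ |C^{T_G1}| / 2.
    """
    if not 0 < f < 1:
        raise ValueError(f"daughter fraction f must lie in (0, 1), got {f}")
    return -f * C_TG1


@dataclass(frozen=True)
class FractionPerturbationSeries:
    """Baseline daughter fraction plus ordered per-generation deviations."""

    f0: float
    delta_f: tuple[float, ...]
    mu: float

    def __post_init__(self) -> None:
        if not 0 < self.f0 < 1:
            raise ValueError(f"f0 must lie in (0, 1), got {self.f0}")
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        for i, df in enumerate(self.delta_f):
            if not 0 < self.f0 + df < 1:
                raise ValueError(
                    f"f0 + delta_f[{i}] = {self.f0 + df} outside (0, 1)"
                )


def phase_shift_from_fraction_series(series: FractionPerturbationSeries) -> float:
    """Lasting division-timing shift implied by a daughter-fraction transient.

    A daughter that receives a larger-than-steady share of the mother's
    volume is effectively further along its growth trajectory, so all its
    subsequent divisions occur *earlier*.  With the delay-positive sign
    convention used throughout this package (Δφ > 0 ⇔ divisions delayed,
    i.e. Δφ = Σ_i (T_div,i − T_div,0)), the shift is

        Δφ = −(1/mu) · ln ∏_i (f0 + Δf_i) / f0

    The product converges within a few generations; at most the first 20
    deviations are used (beyond that any residual increment is far below the
    1e−9 relative level that matters downstream).
    """
    log_sum = 0.0
    for df in series.delta_f[:MAX_GENS]:
        log_sum += math.log1p(df / series.f0)
    return -log_sum / series.mu
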