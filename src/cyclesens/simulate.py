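"""Hybrid simulation of a daughter-cell lineage.

One generation is integrated in two stages: from birth until the budding
event (an up-crossing of the model's G1-cyclin-like observable), then until
the division event (a down-crossing of the mitotic observable).  Volume
grows exponentially throughout (dV/dt = mu·V); at division the daughter
receives the bud volume (V_div − V_bud) and the mother branch is discarded.

Perturbation protocols (sustained steps, single pulses, periodic pulse
trains on named parameters) are applied on absolute simulation time, with
the integration split at every parameter switch so events are located
within homogeneous parameter intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .models.spec import EventRule, ModelSpec
from .phenomenology import CycleMetrics, metrics_from_birth

__all__ = [
    "PerturbationProtocol",
    "EventRecord",
    "LineageTrajectory",
    "ArrestError",
    "ConvergenceError",
    "find_steady_cycle",
    "simulate_lineage",
    "extract_metrics",
    "donated_fractions",
]

#: default integrator tolerances (stiff-capable LSODA throughout).
RTOL = 1e-8
ATOL = 1e-10
#: event-free guard after each stage transition, minutes.
REFRACTORY = 1.0
#: a generation longer than this many mass doubling times counts as arrest.
ARREST_FACTOR = 5.0


class ArrestError(RuntimeError):
    """The cell failed to complete a cycle event within the guard time."""


class ConvergenceError(RuntimeError):
    """The daughter lineage did not settle onto a steady cycle."""


@dataclass(frozen=True)
class PerturbationProtocol:
    """Relative parameter perturbation applied on absolute simulation time.

    ``targets`` lists (parameter name, Δk/k) pairs; all targets switch
    together.  ``kind`` is one of ``none | step | pulse | periodic``.  A step
    persists from ``start_time`` onward; a pulse lasts ``pulse_duration``;
    a periodic train repeats the pulse every ``forcing_period`` minutes.
    """

    kind: str = "none"
    targets: tuple[tuple[str, float], ...] = ()
    start_time: float = 0.0
    pulse_duration: float | None = None
    forcing_period: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "step", "pulse", "periodic"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        for name, delta in self.targets:
            if not 1.0 + delta > 0:
                raise ValueError(f"1 + dk/k must stay positive for {name!r}")
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")
        if self.kind in ("pulse", "periodic"):
            if not (self.pulse_duration and self.pulse_duration > 0):
                raise ValueError(f"{self.kind} protocol needs pulse_duration > 0")
        if self.kind == "periodic":
            if not (self.forcing_period and self.forcing_period > 0):
                raise ValueError("periodic protocol needs forcing_period > 0")

    def validate_against(self, model: ModelSpec) -> None:
        for name, _ in self.targets:
            if name not in model.params:
                raise KeyError(f"protocol targets unknown parameter {name!r}")

    # -- parameter timeline ------------------------------------------------

    @property
    def is_null(self) -> bool:
        """True when the protocol cannot change any parameter value."""
        return (
            self.kind == "none"
            or not self.targets
            or all(d == 0.0 for _, d in self.targets)
        )

    def active(self, t: float) -> bool:
        if self.is_null:
            return False
        if self.kind == "step":
            return t >= self.start_time
        if self.kind == "pulse":
            return self.start_time <= t < self.start_time + self.pulse_duration
        # periodic
        if t < self.start_time:
            return False
        phase = (t - self.start_time) % self.forcing_period
        return phase < self.pulse_duration

    def switch_times(self, t0: float, t1: float) -> list[float]:
        """Strictly increasing parameter switch times inside (t0, t1)."""
        if self.is_null:
            return []
        pts: list[float] = []
        if self.kind == "step":
            pts = [self.start_time]
        elif self.kind == "pulse":
            pts = [self.start_time, self.start_time + self.pulse_duration]
        else:  # periodic
            n0 = max(0, math.floor((t0 - self.start_time) / self.forcing_period) - 1)
            n = n0
            while True:
                on = self.start_time + n * self.forcing_period
                if on > t1:
                    break
                pts.extend([on, on + self.pulse_duration])
                n += 1
        return sorted(t for t in pts if t0 < t < t1)

    def params_at(self, t: float, base: Mapping[str, float]) -> dict[str, float]:
        p = dict(base)
        if self.active(t):
            for name, delta in self.targets:
                p[name] = base[name] * (1.0 + delta)
        return p


_NO_PROTOCOL = PerturbationProtocol()


@dataclass(frozen=True)
class EventRecord:
    generation: int
    kind: str  # birth | bud | division
    time: float  # absolute simulation time, min
    volume: float


@dataclass
class LineageTrajectory:
    """Event stream plus per-generation state of a simulated daughter lineage."""

    mu: float
    events: list[EventRecord] = field(default_factory=list)
    birth_states: list[np.ndarray] = field(default_factory=list)
    arrested: bool = False
    arrest_reason: str = ""
    dense: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def n_generations(self) -> int:
        return sum(1 for e in self.events if e.kind == "division")

    def generation_events(self, i: int) -> dict[str, EventRecord]:
        """Events of generation ``i`` (1-based), keyed by kind."""
        out = {e.kind: e for e in self.events if e.generation == i}
        return out

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "generation": e.generation,
                    "event": e.kind,
                    "time_min": e.time,
                    "volume": e.volume,
                }
                for e in self.events
            ]
        )


# ---------------------------------------------------------------------------
# integration machinery


def _make_rhs(model: ModelSpec, params: Mapping[str, float]):
    mu = params["mu"]
    rhs = model.rhs
    n = model.n_states

    # a fresh output array per call: the integrator may keep references to
    # returned arrays, so the buffer must not be reused
    def f(t: float, z: np.ndarray) -> np.ndarray:
        out = np.empty(n + 1)
        out[:n] = rhs(t, z[:n], z[n], params)
        out[n] = mu * z[n]
        return out

    return f


def _integrate_stage(
    model: ModelSpec,
    protocol: PerturbationProtocol,
    rule: EventRule,
    z0: np.ndarray,
    t0: float,
    deadline: float,
    rtol: float,
    atol: float,
    dense_out: list | None = None,
) -> tuple[float, np.ndarray] | None:
    """Integrate from (t0, z0) until ``rule`` fires or ``deadline`` passes.

    Returns (event time, state at event) or ``None`` on timeout.  The first
    REFRACTORY minutes after t0 are integrated event-free to avoid
    re-triggering on numerical chatter at a stage transition.
    """
    t = t0
    z = np.asarray(z0, dtype=float)
    guard_end = t0 + REFRACTORY

    while t < deadline - 1e-12:
        switches = protocol.switch_times(t, deadline)
        t_stop = switches[0] if switches else deadline
        watch = t >= guard_end - 1e-12
        if not watch and guard_end < t_stop:
            t_stop = guard_end
        params = protocol.params_at((t + t_stop) / 2.0, model.params)

        def event(tt, zz):
            return rule.observable(zz[:-1], zz[-1], params) - rule.threshold

        event.terminal = True
        event.direction = rule.direction

        sol = solve_ivp(
            _make_rhs(model, params),
            (t, t_stop),
            z,
            method="LSODA",
            events=[event] if watch else None,
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed in model {model.name!r} at t={t:.3f}: {sol.message}"
            )
        if dense_out is not None:
            dense_out.append((sol.t, sol.y))
        if watch and sol.t_events and sol.t_events[0].size:
            return float(sol.t_events[0][0]), sol.y_events[0][0]
        t = float(sol.t[-1])
        z = sol.y[:, -1]
    return None


def _simulate_generation(
    model: ModelSpec,
    protocol: PerturbationProtocol,
    z_birth: np.ndarray,
    t_birth: float,
    rtol: float,
    atol: float,
    dense_out: list | None = None,
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """One birth→budding→division pass; raises :class:`ArrestError` on timeout."""
    guard = ARREST_FACTOR * math.log(2.0) / model.mu
    hit = _integrate_stage(
        model, protocol, model.budding_rule, z_birth, t_birth,
        t_birth + guard, rtol, atol, dense_out,
    )
    if hit is None:
        raise ArrestError(f"no budding event within {guard:.0f} min (model {model.name})")
    t_bud, z_bud = hit
    hit = _integrate_stage(
        model, protocol, model.division_rule, z_bud, t_bud,
        t_birth + guard, rtol, atol, dense_out,
    )
    if hit is None:
        raise ArrestError(f"no division event within {guard:.0f} min (model {model.name})")
    t_div, z_div = hit
    return t_bud, z_bud, t_div, z_div


# ---------------------------------------------------------------------------
# public operations


def simulate_lineage(
    model: ModelSpec,
    protocol: PerturbationProtocol | None = None,
    n_generations: int = 6,
    start: tuple[np.ndarray, float] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    keep_dense: bool = False,
) -> LineageTrajectory:
    """Simulate ``n_generations`` daughter cells under a perturbation protocol.

    ``start`` is the (state, volume) at birth of generation 1 — normally the
    converged cycle-start state from :func:`find_steady_cycle`.  Protocol
    times are measured from that birth (t = 0).  If the lineage arrests after
    a perturbation the trajectory is truncated and flagged.
    """
    protocol = protocol or _NO_PROTOCOL
    protocol.validate_against(model)
    if start is None:
        y0 = model.initial_state
        if y0 is None:
            raise ValueError("model has no default initial state; pass start=")
        z = np.append(np.asarray(y0, float), model.initial_volume)
    else:
        y0, V0 = start
        z = np.append(np.asarray(y0, float), V0)

    traj = LineageTrajectory(mu=model.mu)
    t = 0.0
    dense = traj.dense if keep_dense else None
    for gen in range(1, n_generations + 1):
        traj.events.append(EventRecord(gen, "birth", t, z[-1]))
        traj.birth_states.append(z[:-1].copy())
        try:
            t_bud, z_bud, t_div, z_div = _simulate_generation(
                model, protocol, z, t, rtol, atol, dense
            )
        except ArrestError as err:
            traj.arrested = True
            traj.arrest_reason = f"oscillation lost: {err}"
            traj.events.pop()  # incomplete generation carries no events
            traj.birth_states.pop()
            break
        V_bud = z_bud[-1]
        V_div = z_div[-1]
        traj.events.append(EventRecord(gen, "bud", t_bud, V_bud))
        traj.events.append(EventRecord(gen, "division", t_div, V_div))
        y_dau, V_dau = model.division_map(z_div[:-1], V_div, V_bud, model.params)
        z = np.append(y_dau, V_dau)
        t = t_div
    return traj


def extract_metrics(traj: LineageTrajectory) -> list[CycleMetrics]:
    """Per-generation metrics from the event stream only (no model internals).

    Each generation's metrics are taken from its *own* birth, budding and
    division events, so the exponential-growth identities hold exactly in
    every generation, steady or not.
    """
    out: list[CycleMetrics] = []
    for i in range(1, traj.n_generations + 1):
        ev = traj.generation_events(i)
        if not {"birth", "bud", "division"} <= set(ev):
            continue
        b, u, d = ev["birth"], ev["bud"], ev["division"]
        out.append(
            metrics_from_birth(
                V_dau=b.volume,
                T_div=d.time - b.time,
                T_G1=u.time - b.time,
                mu=traj.mu,
            )
        )
    return out


def donated_fractions(traj: LineageTrajectory) -> list[float]:
    """Fraction of the mother's division volume donated to the daughter,
    per generation: (V_div − V_bud) / V_div."""
    out = []
    for i in range(1, traj.n_generations + 1):
        ev = traj.generation_events(i)
        out.append((ev["division"].volume - ev["bud"].volume) / ev["division"].volume)
    return out


def find_steady_cycle(
    model: ModelSpec,
    tol: float = 1e-8,
    max_gens: int = 200,
    rtol: float = RTOL,
    atol: float = ATOL,
    start: tuple[np.ndarray, float] | None = None,
) -> tuple[CycleMetrics, tuple[np.ndarray, float]]:
    """Converge the daughter lineage onto its steady cycle.

    Simulates successive daughter generations until (T_div, V_div) change by
    less than ``tol`` (relative) between generations.  Returns the converged
    metrics and the (state, volume) at birth that reproduces them.

    ``start`` overrides the model's default initial condition; passing the
    converged birth state of a nearby parameterisation (continuation) is the
    reliable way to converge perturbed models.
    """
    if start is not None:
        z = np.append(np.asarray(start[0], float), start[1])
    elif model.initial_state is not None:
        z = np.append(np.asarray(model.initial_state, float), model.initial_volume)
    else:
        raise ValueError("model has no default initial state; pass start=")
    prev: tuple[float, float] | None = None
    for _ in range(max_gens):
        z_birth = z.copy()
        t_bud, z_bud, t_div, z_div = _simulate_generation(
            model, _NO_PROTOCOL, z, 0.0, rtol, atol
        )
        V_div = z_div[-1]
        cur = (t_div, V_div)
        y_dau, V_dau = model.division_map(z_div[:-1], V_div, z_bud[-1], model.params)
        z = np.append(y_dau, V_dau)
        if prev is not None:
            rel = max(abs(cur[0] - prev[0]) / prev[0], abs(cur[1] - prev[1]) / prev[1])
            if rel < tol:
                metrics = metrics_from_birth(
                    V_dau=z_birth[-1], T_div=t_div, T_G1=t_bud, mu=model.mu
                )
                return metrics, (z_birth[:-1], float(z_birth[-1]))
        prev = cur
    raise ConvergenceError(
        f"model {model.name!r}: no steady daughter cycle within {max_gens} generations"
    )
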