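"""Steady-state and dynamic parametric sensitivities of cycle observables.

The static sensitivity of an observable Q to a parameter k is the change of
the steady-cycle value of Q per natural-log unit of k,

    C_k^Q = k dQ/dk = dQ/d(ln k),

computed by a central finite difference in ln k (each evaluation re-converges
the steady daughter cycle, continuing from the basal cycle-start state).
Note that C is *per e-fold* of k: a two-fold parameter increase changes Q by
approximately C·ln 2, not C.

The dynamic sensitivity S_k^{Q_i}(t) is the same derivative for the value of
Q in the i-th generation after a sustained parameter step applied at time t
since division; its time derivative Z_k^{Q_i}(t) is the effect of an
infinitesimally brief perturbation at phase t.  As i grows, S_k^{Q_i}(t)
converges to C_k^Q uniformly in t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models.spec import ModelSpec
from .phenomenology import CycleMetrics
from .simulate import (
    ArrestError,
    ConvergenceError,
    PerturbationProtocol,
    extract_metrics,
    find_steady_cycle,
    simulate_lineage,
)

__all__ = [
    "OBSERVABLES",
    "SensitivityUndefinedError",
    "StaticSensitivity",
    "DynamicSensitivityCurve",
    "static_sensitivity",
    "static_sensitivity_table",
    "sign_concordance",
    "dynamic_sensitivity",
    "dynamic_sensitivity_all",
    "nonmonotonic_fraction",
    "superpose",
    "default_t_grid",
]

OBSERVABLES = CycleMetrics.OBSERVABLES

#: central-difference step in ln k.
DELTA = 0.01
#: default generations tracked after a perturbation.
N_GENS = 6
#: default number of perturbation times per steady cycle.
N_T = 50


class SensitivityUndefinedError(RuntimeError):
    """The perturbed model arrested, so the sensitivity does not exist."""


@dataclass(frozen=True)
class StaticSensitivity:
    parameter: str
    observable: str
    value: float


def _steady(model: ModelSpec, start=None):
    return find_steady_cycle(model, start=start)


def static_sensitivity(
    model: ModelSpec,
    k: str,
    observables: Sequence[str] = OBSERVABLES,
    delta: float = DELTA,
    start: tuple | None = None,
) -> list[StaticSensitivity]:
    """C_k^Q for each requested observable, by central difference in ln k.

    Each half-step rebuilds the steady cycle at k·e^{±delta}, continuing
    from the basal cycle-start state.  Raises
    :class:`SensitivityUndefinedError` if either perturbed model arrests.
    """
    if k not in model.params:
        raise KeyError(f"unknown parameter {k!r} for model {model.name!r}")
    if start is None:
        _, start = _steady(model)
    sides = []
    for sign in (+1.0, -1.0):
        perturbed = model.with_params(**{k: model.params[k] * math.exp(sign * delta)})
        try:
            metrics, _ = _steady(perturbed, start=start)
        except (ArrestError, ConvergenceError) as err:
            raise SensitivityUndefinedError(
                f"steady cycle lost at {k} * e^{sign * delta:+.3f}: {err}"
            ) from err
        sides.append(metrics.as_dict())
    hi, lo = sides
    return [
        StaticSensitivity(k, q, (hi[q] - lo[q]) / (2.0 * delta)) for q in observables
    ]


def static_sensitivity_table(
    model: ModelSpec,
    parameters: Sequence[str] | None = None,
    observables: Sequence[str] = OBSERVABLES,
    delta: float = DELTA,
) -> pd.DataFrame:
    """Long-format table of C_k^Q over parameters × observables.

    Parameters whose perturbation arrests the cycle are recorded with NaN
    values and an error message; the table is still returned.
    """
    parameters = list(parameters) if parameters is not None else list(model.params)
    _, start = _steady(model)
    rows = []
    for k in parameters:
        try:
            for s in static_sensitivity(model, k, observables, delta, start=start):
                rows.append(
                    {"model": model.name, "parameter": k, "observable": s.observable,
                     "C": s.value, "error": ""}
                )
        except SensitivityUndefinedError as err:
            for q in observables:
                rows.append(
                    {"model": model.name, "parameter": k, "observable": q,
                     "C": float("nan"), "error": str(err)}
                )
    return pd.DataFrame(rows)


def sign_concordance(
    table: pd.DataFrame,
    obs_a: str = "V_dau",
    obs_b: str = "T_G1",
    floor: float = 1e-6,
) -> tuple[float, float]:
    """Proportions of parameters whose sensitivities of ``obs_a`` and
    ``obs_b`` share / oppose sign, over parameters with both |C| > floor."""
    wide = table.pivot_table(index="parameter", columns="observable", values="C")
    a, b = wide[obs_a], wide[obs_b]
    mask = (a.abs() > floor) & (b.abs() > floor) & a.notna() & b.notna()
    if not mask.any():
        return (float("nan"), float("nan"))
    same = float(((a[mask] * b[mask]) > 0).mean())
    return same, 1.0 - same


@dataclass
class DynamicSensitivityCurve:
    """S_k^{Q_i}(t) on a perturbation-time grid, with impulse derivative Z.

    ``S`` and ``Z`` have shape (n_gens, n_t); row i-1 is generation i
    (generation 1 contains the perturbation onset).  ``C`` is the static
    limit; grid indices where the perturbed cycle arrested are in
    ``failed_t`` and hold NaN columns.
    """

    parameter: str
    observable: str
    t_grid: np.ndarray
    S: np.ndarray
    Z: np.ndarray
    C: float
    failed_t: list[int] = field(default_factory=list)

    @property
    def n_gens(self) -> int:
        return self.S.shape[0]


def default_t_grid(T_div: float, n_t: int = N_T) -> np.ndarray:
    """Evenly spaced perturbation times covering [0, T_div)."""
    return np.linspace(0.0, T_div, n_t, endpoint=False)


def _centered_diff(S: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Row-wise d/dt with centered interior and one-sided end differences."""
    return np.gradient(S, t, axis=-1)


def _metrics_after_step(
    model: ModelSpec,
    k: str,
    log_step: float,
    t: float,
    n_gens: int,
    start: tuple,
) -> list[CycleMetrics]:
    delta_rel = math.exp(log_step) - 1.0
    protocol = PerturbationProtocol(kind="step", targets=((k, delta_rel),), start_time=t)
    traj = simulate_lineage(model, protocol, n_generations=n_gens, start=start)
    if traj.arrested or traj.n_generations < n_gens:
        raise ArrestError(traj.arrest_reason or "incomplete trajectory")
    return extract_metrics(traj)


def dynamic_sensitivity_all(
    model: ModelSpec,
    k: str,
    t_grid: np.ndarray | None = None,
    n_gens: int = N_GENS,
    delta: float = DELTA,
    start: tuple | None = None,
    steady: CycleMetrics | None = None,
) -> dict[str, DynamicSensitivityCurve]:
    """Dynamic sensitivity curves of *all* observables to parameter ``k``.

    One pair of lineage simulations per grid point serves every observable,
    so requesting all of them costs the same as requesting one.
    """
    if k not in model.params:
        raise KeyError(f"unknown parameter {k!r} for model {model.name!r}")
    if start is None or steady is None:
        steady, start = _steady(model)
    if t_grid is None:
        t_grid = default_t_grid(steady.T_div)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must contain at least one perturbation time")

    S = {q: np.full((n_gens, t_grid.size), np.nan) for q in OBSERVABLES}
    failed: list[int] = []
    for j, t in enumerate(t_grid):
        try:
            hi = _metrics_after_step(model, k, +delta, float(t), n_gens, start)
            lo = _metrics_after_step(model, k, -delta, float(t), n_gens, start)
        except ArrestError:
            failed.append(j)
            continue
        for q in OBSERVABLES:
            for i in range(n_gens):
                S[q][i, j] = (
                    getattr(hi[i], q) - getattr(lo[i], q)
                ) / (2.0 * delta)

    # static limits for every observable, for the Eq-5 style convergence check
    try:
        stat = {s.observable: s.value for s in static_sensitivity(model, k, delta=delta, start=start)}
    except SensitivityUndefinedError:
        stat = {q: float("nan") for q in OBSERVABLES}

    return {
        q: DynamicSensitivityCurve(
            parameter=k,
            observable=q,
            t_grid=t_grid,
            S=S[q],
            Z=_centered_diff(S[q], t_grid),
            C=stat[q],
            failed_t=list(failed),
        )
        for q in OBSERVABLES
    }


def dynamic_sensitivity(
    model: ModelSpec,
    k: str,
    observable: str = "T_G1",
    t_grid: np.ndarray | None = None,
    n_gens: int = N_GENS,
    delta: float = DELTA,
    start: tuple | None = None,
    steady: CycleMetrics | None = None,
) -> DynamicSensitivityCurve:
    """Dynamic sensitivity curve S_k^{Q_i}(t) for one observable."""
    if observable not in OBSERVABLES:
        raise KeyError(f"unknown observable {observable!r}")
    return dynamic_sensitivity_all(
        model, k, t_grid, n_gens, delta, start=start, steady=steady
    )[observable]


def _sequence_is_nonmonotonic(seq: np.ndarray, eps: float) -> bool:
    """True when successive differences change sign with magnitude > eps."""
    d = np.diff(seq)
    d = d[np.abs(d) > eps]
    if d.size < 2:
        return False
    return bool(np.any(np.sign(d[1:]) != np.sign(d[:-1])))


def nonmonotonic_fraction(
    model: ModelSpec,
    observable: str = "T_G1",
    parameters: Sequence[str] | None = None,
    t_grid: np.ndarray | None = None,
    n_gens: int = N_GENS,
    delta: float = DELTA,
    eps_rel: float = 1e-3,
    include_baseline: bool = True,
) -> tuple[dict[str, float], float]:
    """Fraction of the cycle over which the response down generations,
    {S_k^{Q_i}(t)}_i extended by its converged limit C, is nonmonotonic.

    With ``include_baseline`` (default) the sequence starts at the
    pre-perturbation value 0, so a generation-1 overshoot that later
    reverses — the canonical transient of these models — counts as
    nonmonotonic even when generations 1..n then approach the limit
    steadily.  Set it to False to judge generations 1..n and the limit
    only.

    The sign-change tolerance is ``eps_rel`` times the curve family's
    maximum amplitude, so numerical ripple is not counted.  Returns the
    per-parameter fractions and their average; parameters with undefined
    sensitivities are excluded (reported as NaN).
    """
    parameters = list(parameters) if parameters is not None else list(model.params)
    steady, start = _steady(model)
    if t_grid is None:
        t_grid = default_t_grid(steady.T_div)
    per_param: dict[str, float] = {}
    for k in parameters:
        curve = dynamic_sensitivity(
            model, k, observable, t_grid, n_gens, delta, start=start, steady=steady
        )
        rows = [curve.S, np.full((1, curve.t_grid.size), curve.C)]
        if include_baseline:
            rows.insert(0, np.zeros((1, curve.t_grid.size)))
        stack = np.vstack(rows)
        finite = np.isfinite(stack).all(axis=0)
        if not finite.any() or not np.isfinite(curve.C):
            per_param[k] = float("nan")
            continue
        eps = eps_rel * np.nanmax(np.abs(stack))
        flags = [
            _sequence_is_nonmonotonic(stack[:, j], eps)
            for j in range(stack.shape[1])
            if finite[j]
        ]
        per_param[k] = float(np.mean(flags))
    valid = [v for v in per_param.values() if not math.isnan(v)]
    avg = float(np.mean(valid)) if valid else float("nan")
    return per_param, avg


def superpose(
    curves: Sequence[DynamicSensitivityCurve],
    deltas: Sequence[tuple[str, float]],
    t: float,
) -> np.ndarray:
    """Linear superposition of per-parameter responses at perturbation time t.

    ΔQ_i(t) = Σ_j (Δk_j/k_j) · S_{k_j}^{Q_i}(t), interpolated on the shared
    t grid.  All curves must share observable and grid.
    """
    if not curves:
        raise ValueError("need at least one curve")
    obs = curves[0].observable
    grid = curves[0].t_grid
    by_param = {}
    for c in curves:
        if c.observable != obs or c.t_grid.shape != grid.shape or not np.allclose(c.t_grid, grid):
            raise ValueError("curves must share observable and t_grid")
        by_param[c.parameter] = c
    total = np.zeros(curves[0].n_gens)
    for name, rel in deltas:
        if name not in by_param:
            raise KeyError(f"no curve supplied for parameter {name!r}")
        c = by_param[name]
        for i in range(c.n_gens):
            total[i] += rel * np.interp(t, grid, c.S[i])
    return total
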