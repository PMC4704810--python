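"""Uniform contract for growth-coupled cell-cycle oscillator models.

A model is an ODE system for intensive cell-cycle components, coupled to an
exponentially growing cell volume (dV/dt = mu·V).  Volume feeds back on the
dynamics through volume-scaled synthesis terms; the dynamics in turn set the
timing of the two cell-cycle events:

* budding — a G1-cyclin-like observable crosses a threshold upward;
* division — a mitotic-cyclin-like observable crosses a threshold downward.

At division the daughter receives the bud's volume (V_div − V_bud) and, by
default, inherits the intensive state unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = ["EventRule", "ModelSpec", "RegulationChannel", "default_division_map"]

Observable = Callable[[np.ndarray, float, Mapping[str, float]], float]


@dataclass(frozen=True)
class EventRule:
    """Threshold crossing of an observable in a fixed direction."""

    observable: Observable
    threshold: float
    direction: int  # +1 for up-crossing, -1 for down-crossing
    name: str = ""

    def gap(self, y: np.ndarray, V: float, params: Mapping[str, float]) -> float:
        return self.observable(y, V, params) - self.threshold


def default_division_map(
    y: np.ndarray, V_div: float, V_bud: float, params: Mapping[str, float]
) -> tuple[np.ndarray, float]:
    """Concentrations pass to the daughter unchanged; volume becomes the bud."""
    return y.copy(), V_div - V_bud


@dataclass
class ModelSpec:
    """A registered cell-cycle oscillator behind the uniform contract.

    ``rhs(t, y, V, params)`` returns the state derivative; volume dynamics
    (dV/dt = mu·V) are supplied by the simulator and must not be included.
    """

    name: str
    state_names: tuple[str, ...]
    params: dict[str, float]
    rhs: Callable[[float, np.ndarray, float, Mapping[str, float]], np.ndarray]
    budding_rule: EventRule
    division_rule: EventRule
    size_coupling: str
    division_map: Callable[..., tuple[np.ndarray, float]] = default_division_map
    initial_state: np.ndarray | None = None
    initial_volume: float = 1.0
    stiff: bool = False
    param_descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "mu" not in self.params:
            raise ValueError("every model must carry a growth-rate parameter 'mu'")
        if not self.params["mu"] > 0:
            raise ValueError("growth rate mu must be positive")

    @property
    def mu(self) -> float:
        return self.params["mu"]

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def with_params(self, **updates: float) -> "ModelSpec":
        """Copy of this model with named parameter values replaced."""
        unknown = set(updates) - set(self.params)
        if unknown:
            raise KeyError(f"unknown parameter(s) for model {self.name!r}: {sorted(unknown)}")
        new = dict(self.params)
        new.update(updates)
        return ModelSpec(
            name=self.name,
            state_names=self.state_names,
            params=new,
            rhs=self.rhs,
            budding_rule=self.budding_rule,
            division_rule=self.division_rule,
            size_coupling=self.size_coupling,
            division_map=self.division_map,
            initial_state=None if self.initial_state is None else self.initial_state.copy(),
            initial_volume=self.initial_volume,
            stiff=self.stiff,
            param_descriptions=dict(self.param_descriptions),
        )

    def parameter_table(self) -> list[tuple[str, float, str]]:
        """Ordered (name, basal value, description) rows for every parameter."""
        return [
            (k, v, self.param_descriptions.get(k, "")) for k, v in self.params.items()
        ]


@dataclass(frozen=True)
class RegulationChannel:
    """A signalling channel: coupled parameters moved by one shared multiplier.

    ``sign`` is the direction of the relative parameter change for an
    *increasing* signal (+1: parameters go up with the signal, −1: down).
    """

    name: str
    parameters: tuple[str, ...]
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("channel sign must be +1 or -1")
        if not self.parameters:
            raise ValueError("channel must name at least one parameter")

    def validate_against(self, model: ModelSpec) -> None:
        missing = [p for p in self.parameters if p not in model.params]
        if missing:
            raise ValueError(
                f"model {model.name!r} lacks channel parameter(s): {missing}"
            )
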