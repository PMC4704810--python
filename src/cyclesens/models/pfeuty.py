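"""Minimal two-variable cell-cycle oscillator (Pfeuty-style).

Two quasi-molecular components drive the cycle.  ``X`` aggregates the G1/S
activators: it is self-activating (the Start positive feedback of the
Cln1,2–SBF loop) and driven by a volume-scaled synthesis term ``s_x2``, the
Cln3-synthesis analogue that communicates cell size to the cycle.  ``Y``
aggregates mitotic activity: it integrates X and represses X synthesis,
closing the negative feedback loop that makes the system a relaxation
oscillator.

    dX/dt = (s_x1·X²/(K_x²+X²) + s_x2·V) · K_y⁶/(K_y⁶+Y⁶) − d_x·(1+(Y/K_y)²)·X
    dY/dt = s_y·X⁴/(K_x⁴+X⁴) − d_y·Y

Y both represses X synthesis and promotes X turnover (mitotic CDK activity
inactivates the G1/S machinery); the second coupling keeps the G1/S switch
off during mitotic exit at large cell volumes, which makes the limit cycle
robust to parameter perturbation.

In G1 (Y low) the X switch is off and X sits on its low branch; volume
growth raises the drive ``s_x2·V`` until the low branch disappears in a
saddle-node and X jumps high — the size-gated Start transition.  Budding
fires when X rises through ``THETA_BUD``.  High X drives Y up; Y represses
X synthesis, X collapses, and Y decays until it falls through ``THETA_DIV``:
division.  Thresholds are structural constants, not parameters.

The model has 8 parameters including the growth rate ``mu``; rate constants
are uniformly rescaled with ``mu`` so the cycle keeps a fixed shape in units
of the mass doubling time at any growth rate.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .spec import EventRule, ModelSpec

__all__ = ["build", "BASAL_MU"]

#: basal growth rate: 100-minute mass doubling time.
BASAL_MU = math.log(2.0) / 100.0

# Budding / division thresholds (structural constants of the event rules).
THETA_BUD = 1.5
THETA_DIV = 0.30

#: Hill exponents (structural).
_H_REP = 6.0
_H_ACT = 4.0

# Basal kinetic parameters at BASAL_MU; rates are 1/min, K's dimensionless.
_BASAL_PARAMS = {
    "s_x1": 2.0,
    "s_x2": 0.00024,
    "d_x": 0.30,
    "s_y": 0.016,
    "d_y": 0.012,
    "K_x": 1.0,
    "K_y": 0.40,
    "mu": BASAL_MU,
}

#: parameters with units of 1/min, uniformly rescaled with the growth rate.
_RATE_PARAMS = ("s_x1", "s_x2", "d_x", "s_y", "d_y")

_DESCRIPTIONS = {
    "s_x1": "maximal self-activated synthesis rate of the G1/S activator X (1/min)",
    "s_x2": "volume-scaled synthesis rate of X; Cln3-synthesis analogue (1/(min*vol))",
    "d_x": "basal turnover rate of X, stimulated by Y (1/min)",
    "s_y": "maximal X-activated synthesis rate of mitotic activity Y (1/min)",
    "d_y": "first-order decay rate of Y (1/min)",
    "K_x": "X level at half-maximal self-activation",
    "K_y": "Y level at half-maximal repression of X synthesis",
    "mu": "exponential volume growth rate (1/min)",
}


def _rhs(t: float, y: np.ndarray, V: float, p: Mapping[str, float]) -> np.ndarray:
    X, Y = y
    X2 = X * X
    Kx2 = p["K_x"] * p["K_x"]
    Kyh = p["K_y"] ** _H_REP
    Kxa = p["K_x"] ** _H_ACT
    Xa = X**_H_ACT
    repression = Kyh / (Kyh + Y**_H_REP)
    drive = p["s_x1"] * X2 / (Kx2 + X2) + p["s_x2"] * V
    yk = Y / p["K_y"]
    dX = drive * repression - p["d_x"] * (1.0 + yk * yk) * X
    dY = p["s_y"] * Xa / (Kxa + Xa) - p["d_y"] * Y
    return np.array([dX, dY])


def build(mu: float | None = None, overrides: Mapping[str, float] | None = None) -> ModelSpec:
    """Build the Pfeuty-style model at growth rate ``mu`` (default basal).

    All rate parameters are uniformly rescaled by ``mu / BASAL_MU`` so the
    oscillator period tracks the mass doubling time; explicit ``overrides``
    are applied after rescaling.
    """
    mu = BASAL_MU if mu is None else mu
    if not mu > 0:
        raise ValueError(f"growth rate mu must be positive, got {mu}")
    scale = mu / BASAL_MU
    params = dict(_BASAL_PARAMS)
    for name in _RATE_PARAMS:
        params[name] *= scale
    params["mu"] = mu
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise KeyError(f"unknown parameter(s) for model 'pfeuty': {sorted(unknown)}")
        params.update(overrides)

    return ModelSpec(
        name="pfeuty",
        state_names=("X", "Y"),
        params=params,
        rhs=_rhs,
        budding_rule=EventRule(
            observable=lambda y, V, p: y[0],
            threshold=THETA_BUD,
            direction=+1,
            name="budding (X up)",
        ),
        division_rule=EventRule(
            observable=lambda y, V, p: y[1],
            threshold=THETA_DIV,
            direction=-1,
            name="division (Y down)",
        ),
        size_coupling="X synthesis scales with volume (s_x2*V term)",
        initial_state=np.array([0.2, 0.4]),
        initial_volume=125.0,
        stiff=False,
        param_descriptions=dict(_DESCRIPTIONS),
    )
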