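"""Mid-size budding-yeast cell-cycle network (Chen-style), 9 variables.

A phenomenological ODE rendition of the classic budding-yeast regulatory
architecture: the SBF → Cln2 Start switch gated by cell size, the
Clb5/Clb2 cyclin waves antagonised by Sic1 and Cdh1, the Mcm1-driven
mitotic positive feedback, and the Cdc20 → Cdc14 exit module that restores
the G1 state.  State variables (all intensive):

    SBF    G1/S transcription-factor activity (fraction, 0–1)
    Cln2   G1/S cyclin–CDK activity; budding fires on its up-crossing
    Clb5   S-phase cyclin (total)
    Clb2   mitotic cyclin (total); division fires when it falls back
           through a threshold at mitotic exit
    Mcm1   mitotic transcription-factor activity (fraction)
    Sic1   CDK stoichiometric inhibitor
    Cdh1   APC adaptor active in G1 (fraction)
    Cdc20  anaphase APC adaptor
    Cdc14  mitotic-exit phosphatase (fraction of releasable pool)

Size coupling: every protein-synthesis flux scales with cell volume, so the
``k_cln3`` volume term in the SBF activation drive acts as the
Cln3-size-sensor analogue that triggers Start.  Transcription-factor and
adaptor activities are modelled as saturating (Goldbeter–Koshland style)
interconversions.  The model has 63 parameters including the growth rate
``mu``.

Activities inhibited by Sic1 enter as B5a = Clb5/(1 + Sic1/J_s1_b5) and
B2a = Clb2/(1 + Sic1/J_s1_b2) — a rapid-buffering approximation of
stoichiometric inhibition.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .spec import EventRule, ModelSpec

__all__ = ["build", "BASAL_MU"]

#: basal growth rate: 100-minute mass doubling time.
BASAL_MU = math.log(2.0) / 100.0

# Event thresholds (structural).
THETA_BUD = 0.5   # Cln2 rising through this marks Start/budding
THETA_DIV = 0.30  # total Clb2 falling through this marks division

STATE_NAMES = (
    "SBF", "Cln2", "Clb5", "Clb2", "Mcm1", "Sic1", "Cdh1", "Cdc20", "Cdc14"
)

_BASAL_PARAMS = {
    # SBF switch: activated by Cln2, Clb5 and the Cln3-like size signal,
    # inactivated basally and by mitotic Clb2
    "k_a_sbf": 1.0, "k_cln3": 0.0016667, "k_cln3p": 0.002, "e_b5_sbf": 0.02,
    "J_a_sbf": 0.05, "k_i_sbf": 0.2, "k_i_sbf_b2": 2.0, "k_i_sbf_m1": 0.8,
    "J_i_sbf": 0.05,
    # Cln2
    "k_s_c2p": 5.5556e-05, "k_s_c2": 0.0030556, "k_d_c2": 0.25, "k_d_c2_b2": 0.02,
    # Clb5
    "k_s_b5p": 5.5556e-05, "k_s_b5": 0.0016667, "k_d_b5": 0.08, "k_d_b5_20": 0.5,
    "k_d_b5_h1": 0.02,
    # Clb2
    "k_s_b2p": 0.00011111, "k_s_b2": 0.0016667, "k_d_b2": 0.015, "k_d_b2_h1": 0.4,
    "k_d_b2_20": 2.0, "J_d_b2": 6.0,
    # Mcm1 switch
    "k_a_mcm": 1.0, "e3_b5": 0.01, "J_a_mcm": 0.05, "k_i_mcm": 0.25,
    "k_i_mcm_14": 0.02, "J_i_mcm": 0.05,
    # Sic1
    "k_s_s1": 0.01, "k_s_s1_14": 0.5, "k_s_s1_m1": 0.002, "k_s_s1_v": 1.3889e-05,
    "k_d_s1p": 0.004, "k_d_s1": 0.4, "e_c2": 1.0, "e_b5": 1.0, "e_b2": 0.5,
    "e_c3": 5.5556e-05,
    # Cdh1 switch
    "k_a_h1": 0.05, "k_a_h1_14": 2.0, "J_a_h1": 0.03, "k_i_h1": 1.2,
    "k_i_h1_p": 0.02, "e2_c2": 0.1, "e2_b5": 0.6, "e2_b2": 1.0, "J_i_h1": 0.03,
    # Cdc20
    "k_s_20p": 0.001, "k_s_20": 0.015, "k_s_20_m1": 0.005, "J_s_20": 0.5,
    "k_d_20": 0.06, "k_d_20_h1": 0.03,
    # Cdc14
    "k_a_14": 2.0, "k_a_14_b2": 0.1, "J_a_14": 1.0, "k_i_14": 0.2, "C14T": 1.0,
    # Sic1 buffering of cyclin activity
    "J_s1_b2": 0.3, "J_s1_b5": 0.3,
    # growth
    "mu": BASAL_MU,
}

_DESCRIPTIONS = {
    "k_a_sbf": "SBF activation rate per unit of activating CDK signal (1/min)",
    "k_cln3": "volume-scaled Cln3-like drive of SBF activation; the size-sensor analogue",
    "k_cln3p": "size-independent basal drive of SBF activation",
    "e_b5_sbf": "weight of Clb5 activity in the SBF activation signal",
    "J_a_sbf": "saturation constant of SBF activation",
    "k_i_sbf": "basal SBF inactivation rate (1/min)",
    "k_i_sbf_b2": "Clb2-dependent SBF inactivation rate (1/min per activity)",
    "k_i_sbf_m1": "Mcm1-dependent SBF inactivation rate (1/min per activity); keeps the G1/S program off until mitotic exit completes",
    "J_i_sbf": "saturation constant of SBF inactivation",
    "k_s_c2p": "SBF-independent Cln2 synthesis rate, scales with volume",
    "k_s_c2": "SBF-driven Cln2 synthesis rate, scales with volume",
    "k_d_c2": "basal Cln2 degradation rate (1/min)",
    "k_d_c2_b2": "Clb2-stimulated Cln2 degradation (1/min per activity)",
    "k_s_b5p": "SBF-independent Clb5 synthesis rate, scales with volume",
    "k_s_b5": "SBF-driven Clb5 synthesis rate, scales with volume",
    "k_d_b5": "basal Clb5 degradation rate (1/min)",
    "k_d_b5_20": "Cdc20-mediated Clb5 degradation (1/min per Cdc20)",
    "k_d_b5_h1": "Cdh1-mediated Clb5 degradation (1/min per Cdh1)",
    "k_s_b2p": "Mcm1-independent Clb2 synthesis rate, scales with volume",
    "k_s_b2": "Mcm1-driven Clb2 synthesis rate, scales with volume; mitotic-cyclin synthesis",
    "k_d_b2": "basal Clb2 degradation rate (1/min)",
    "k_d_b2_h1": "Cdh1-mediated Clb2 degradation (1/min per Cdh1)",
    "k_d_b2_20": "Cdc20-mediated Clb2 degradation (1/min per Cdc20)",
    "J_d_b2": "saturation constant of APC-mediated Clb2 degradation",
    "k_a_mcm": "Mcm1 activation rate per unit active Clb2 (1/min)",
    "e3_b5": "weight of Clb5 activity in Mcm1 activation",
    "J_a_mcm": "saturation constant of Mcm1 activation",
    "k_i_mcm": "basal Mcm1 inactivation rate (1/min)",
    "k_i_mcm_14": "Cdc14-stimulated Mcm1 inactivation (1/min per Cdc14)",
    "J_i_mcm": "saturation constant of Mcm1 inactivation",
    "k_s_s1": "basal Sic1 synthesis rate",
    "k_s_s1_14": "Cdc14-promoted Sic1 synthesis/stabilisation rate",
    "k_s_s1_m1": "Mcm1(Swi5)-driven Sic1 synthesis rate",
    "k_s_s1_v": "volume-scaled Sic1 synthesis rate",
    "k_d_s1p": "basal Sic1 turnover rate (1/min)",
    "k_d_s1": "phosphorylation-dependent Sic1 degradation rate (1/min per kinase unit)",
    "e_c2": "weight of Cln2 in Sic1-phosphorylating activity",
    "e_b5": "weight of active Clb5 in Sic1-phosphorylating activity",
    "e_b2": "weight of active Clb2 in Sic1-phosphorylating activity",
    "e_c3": "weight of the volume-scaled Cln3-like activity in Sic1 phosphorylation",
    "k_a_h1": "basal Cdh1 activation rate (1/min)",
    "k_a_h1_14": "Cdc14-driven Cdh1 activation rate (1/min per Cdc14)",
    "J_a_h1": "saturation constant of Cdh1 activation",
    "k_i_h1": "CDK-driven Cdh1 inactivation rate (1/min per kinase unit)",
    "k_i_h1_p": "constitutive Cdh1 inactivation rate (1/min)",
    "e2_c2": "weight of Cln2 in Cdh1-inactivating activity",
    "e2_b5": "weight of active Clb5 in Cdh1-inactivating activity",
    "e2_b2": "weight of active Clb2 in Cdh1-inactivating activity",
    "J_i_h1": "saturation constant of Cdh1 inactivation",
    "k_s_20p": "basal Cdc20 synthesis rate",
    "k_s_20": "Clb2-activated Cdc20 synthesis/activation rate",
    "k_s_20_m1": "Mcm1-driven Cdc20 synthesis rate",
    "J_s_20": "active-Clb2 level at half-maximal Cdc20 activation",
    "k_d_20": "basal Cdc20 degradation rate (1/min)",
    "k_d_20_h1": "Cdh1-mediated Cdc20 degradation (1/min per Cdh1)",
    "k_a_14": "Cdc20-driven Cdc14 release rate (1/min per Cdc20)",
    "k_a_14_b2": "Clb2-assisted Cdc14 release rate (1/min per activity)",
    "J_a_14": "saturation constant of Cdc14 release",
    "k_i_14": "Cdc14 resequestration rate (1/min)",
    "C14T": "total releasable Cdc14 pool",
    "J_s1_b2": "Sic1 level halving active Clb2",
    "J_s1_b5": "Sic1 level halving active Clb5",
    "mu": "exponential volume growth rate (1/min)",
}

#: initial condition: a small newborn G1 cell (Cdh1 on, Sic1 high).
_INITIAL_STATE = np.array([0.0, 0.01, 0.01, 0.05, 0.0, 0.8, 0.95, 0.01, 0.05])


def _active_clb(y: np.ndarray, p: Mapping[str, float]) -> tuple[float, float]:
    Sic1 = y[5]
    B5a = y[2] / (1.0 + Sic1 / p["J_s1_b5"])
    B2a = y[3] / (1.0 + Sic1 / p["J_s1_b2"])
    return B5a, B2a


def _gk(act: float, inact: float, Ja: float, Ji: float, x: float) -> float:
    return act * (1.0 - x) / (Ja + 1.0 - x) - inact * x / (Ji + x)


def _rhs(t: float, y: np.ndarray, V: float, p: Mapping[str, float]) -> np.ndarray:
    SBF, Cln2, Clb5, Clb2, Mcm1, Sic1, Cdh1, Cdc20, Cdc14 = y
    B5a, B2a = _active_clb(y, p)

    sbf_act = p["k_a_sbf"] * (
        Cln2 + p["e_b5_sbf"] * B5a + p["k_cln3"] * V + p["k_cln3p"]
    )
    sbf_inact = p["k_i_sbf"] + p["k_i_sbf_b2"] * B2a + p["k_i_sbf_m1"] * Mcm1
    dSBF = _gk(sbf_act, sbf_inact, p["J_a_sbf"], p["J_i_sbf"], SBF)

    dCln2 = (p["k_s_c2p"] + p["k_s_c2"] * SBF) * V - (
        p["k_d_c2"] + p["k_d_c2_b2"] * B2a
    ) * Cln2

    dClb5 = (p["k_s_b5p"] + p["k_s_b5"] * SBF) * V - (
        p["k_d_b5"] + p["k_d_b5_20"] * Cdc20 + p["k_d_b5_h1"] * Cdh1
    ) * Clb5

    apc_b2 = (p["k_d_b2_h1"] * Cdh1 + p["k_d_b2_20"] * Cdc20) * (
        p["J_d_b2"] / (p["J_d_b2"] + Clb2)
    )
    dClb2 = (p["k_s_b2p"] + p["k_s_b2"] * Mcm1) * V - (p["k_d_b2"] + apc_b2) * Clb2

    dMcm1 = _gk(
        p["k_a_mcm"] * (B2a + p["e3_b5"] * B5a),
        p["k_i_mcm"] + p["k_i_mcm_14"] * Cdc14,
        p["J_a_mcm"], p["J_i_mcm"], Mcm1,
    )

    kin_s1 = p["e_c2"] * Cln2 + p["e_b5"] * B5a + p["e_b2"] * B2a + p["e_c3"] * V
    dSic1 = (
        p["k_s_s1"] + p["k_s_s1_14"] * Cdc14 + p["k_s_s1_m1"] * Mcm1
        + p["k_s_s1_v"] * V
    ) - (p["k_d_s1p"] + p["k_d_s1"] * kin_s1) * Sic1

    kin_h1 = p["e2_c2"] * Cln2 + p["e2_b5"] * B5a + p["e2_b2"] * B2a
    dCdh1 = _gk(
        p["k_a_h1"] + p["k_a_h1_14"] * Cdc14,
        p["k_i_h1"] * kin_h1 + p["k_i_h1_p"],
        p["J_a_h1"], p["J_i_h1"], Cdh1,
    )

    b2a4 = B2a**4
    dCdc20 = (
        p["k_s_20p"] + p["k_s_20"] * b2a4 / (p["J_s_20"] ** 4 + b2a4)
        + p["k_s_20_m1"] * Mcm1
    ) - (p["k_d_20"] + p["k_d_20_h1"] * Cdh1) * Cdc20

    free = p["C14T"] - Cdc14
    dCdc14 = (
        p["k_a_14"] * Cdc20 + p["k_a_14_b2"] * B2a
    ) * free / (p["J_a_14"] + free) - p["k_i_14"] * Cdc14

    return np.array(
        [dSBF, dCln2, dClb5, dClb2, dMcm1, dSic1, dCdh1, dCdc20, dCdc14]
    )


def build(mu: float | None = None, overrides: Mapping[str, float] | None = None) -> ModelSpec:
    """Build the Chen-style model at growth rate ``mu`` (default basal)."""
    mu = BASAL_MU if mu is None else mu
    if not mu > 0:
        raise ValueError(f"growth rate mu must be positive, got {mu}")
    params = dict(_BASAL_PARAMS)
    params["mu"] = mu
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise KeyError(f"unknown parameter(s) for model 'chen': {sorted(unknown)}")
        params.update(overrides)

    return ModelSpec(
        name="chen",
        state_names=STATE_NAMES,
        params=params,
        rhs=_rhs,
        budding_rule=EventRule(
            observable=lambda y, V, p: y[1],
            threshold=THETA_BUD,
            direction=+1,
            name="budding (Cln2 up)",
        ),
        division_rule=EventRule(
            observable=lambda y, V, p: y[3],
            threshold=THETA_DIV,
            direction=-1,
            name="division (total Clb2 down)",
        ),
        size_coupling="all protein synthesis fluxes scale with volume; "
        "k_cln3*V is the Cln3-like size signal driving Start",
        initial_state=_INITIAL_STATE.copy(),
        initial_volume=36.0,
        stiff=True,
        param_descriptions=dict(_DESCRIPTIONS),
    )
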