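"""Detailed mass-action cell-cycle model with multisite phosphorylation
(Barik-style), 61 species and 70 parameters.

The network represents transcription, translation and protein interactions
of the core budding-yeast machinery with elementary (mass-action) kinetics;
ultrasensitive switches arise from multisite phosphorylation chains and
stoichiometric sequestration rather than from Hill functions.

Modules
-------
* **Size sensing / Start** — Cln3 and Bck2 are translated at rates
  proportional to cell volume; they (and ClbS, closing a positive feedback)
  phosphorylate Whi5, releasing SBF from the inhibitory SBF:Whi5 complex.
  Free SBF transcribes the G1/S cyclin class ClbS (``k_s_mbS``); budding
  fires when free ClbS rises through a threshold.
* **Sic1 multisite chain** — Sic1 (8 phospho-states) binds and inhibits
  both cyclin classes; cyclin-dependent phosphorylation down the chain ends
  in degradation of the fully phosphorylated form, releasing the cyclins —
  the ultrasensitive trigger for S/M progression.
* **Mitosis** — the mitotic cyclin class ClbM activates its own
  transcription factor Mcm1 (positive feedback); division fires when free
  ClbM falls back through a threshold.
* **Exit** — ClbM phosphorylates Net1 (5 phospho-states, free and in the
  RENT complex with Cdc14); phosphorylated RENT releases Cdc14, which
  activates Swi5 (Sic1 resynthesis) and Cdh1 (ClbM destruction) while
  Cdc20, transcribed by Mcm1 and activated by ClbM, degrades the cyclins.
  The phosphatase Ht1 reverses Net1 phosphorylation (``k_d_t1`` on free
  Net1, ``k_d_nt`` in the RENT complex) and resets Whi5.

The three glucose-signalling channels of the attainable-region case study
act on ``k_s_n3`` (Cln3 translation, up), ``k_s_mbS`` (ClbS transcription,
down) and the pair ``k_d_t1``/``k_d_nt`` (Net1 dephosphorylation, up,
moved proportionally).
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .spec import EventRule, ModelSpec

__all__ = ["build", "BASAL_MU", "N_SIC1", "N_NET1"]

#: basal growth rate: 100-minute mass doubling time.
BASAL_MU = math.log(2.0) / 100.0

#: phospho-states: Sic1 has sites 0..7, Net1 has sites 0..4.
N_SIC1 = 8
N_NET1 = 5

# Event thresholds (structural).
THETA_BUD = 0.20  # free ClbS rising through this marks Start/budding
THETA_DIV = 0.20  # free ClbM falling through this marks division

# ---------------------------------------------------------------------------
# state layout

_MRNAS = ["m_n3", "m_bS", "m_bM", "m_s1", "m_20", "m_h1", "m_swi5", "m_whi5", "m_net1"]
STATE_NAMES = tuple(
    _MRNAS
    + ["Cln3", "Bck2", "Whi5", "Whi5P", "SBF", "SBFWhi5", "ClbS", "ClbM"]
    + [f"Sic1_p{i}" for i in range(N_SIC1)]
    + [f"ClbS_Sic1_p{i}" for i in range(N_SIC1)]
    + [f"ClbM_Sic1_p{i}" for i in range(N_SIC1)]
    + ["Cdh1a", "Cdh1P", "Cdc20i", "Cdc20a", "Mcm1i", "Mcm1a", "Swi5i", "Swi5a"]
    + [f"Net1_p{i}" for i in range(N_NET1)]
    + [f"RENT_p{i}" for i in range(N_NET1)]
    + ["Cdc14", "Ht1"]
)

_I = {name: i for i, name in enumerate(STATE_NAMES)}
_S1F = slice(_I["Sic1_p0"], _I["Sic1_p0"] + N_SIC1)          # free Sic1 chain
_S1S = slice(_I["ClbS_Sic1_p0"], _I["ClbS_Sic1_p0"] + N_SIC1)  # ClbS-bound
_S1M = slice(_I["ClbM_Sic1_p0"], _I["ClbM_Sic1_p0"] + N_SIC1)  # ClbM-bound
_NETF = slice(_I["Net1_p0"], _I["Net1_p0"] + N_NET1)
_RENT = slice(_I["RENT_p0"], _I["RENT_p0"] + N_NET1)

#: RENT dissociation weights: only well-phosphorylated complexes release
#: Cdc14 (linear in the number of phosphorylated sites).
_W_RENT = np.arange(N_NET1) / (N_NET1 - 1)

_BASAL_PARAMS = {
    # transcription
    "k_s_mn3": 0.05, "k_s_mbS": 0.10, "k_s_mbM": 0.25, "k_s_mbMp": 0.0015,
    "k_s_ms1": 0.30, "k_s_m20": 0.03,
    "k_s_mh1": 0.02, "k_s_mswi5": 0.02, "k_s_mwhi5": 0.02, "k_s_mnet1": 0.02,
    # mRNA turnover
    "k_d_mn3": 0.10, "k_d_mbS": 0.10, "k_d_mbM": 0.10, "k_d_ms1": 0.10,
    "k_d_m20": 0.10, "k_d_m": 0.05,
    # translation (Cln3 and Bck2 scale with volume: the size sensors)
    "k_s_n3": 0.00171569, "k_s_bck2": 0.000343139, "k_s_bS": 0.25, "k_s_bM": 0.25,
    "k_s_s1": 0.25, "k_s_20": 0.12, "k_s_h1": 0.01, "k_s_swi5": 0.10,
    "k_s_whi5": 0.012, "k_s_net1": 0.02,
    # protein turnover
    "k_d_n3": 0.10, "k_d_bck2": 0.05, "k_d_bS": 0.05, "k_d_bM": 0.02,
    "k_d_s1": 0.01, "k_d_20p": 0.08, "k_d_h1": 0.01, "k_d_swi5": 0.05,
    "k_d_whi5": 0.01, "k_d_net1": 0.01,
    # APC-mediated cyclin destruction
    "k_d_bM_h1": 1.0, "k_d_bM_20": 1.5, "k_d_bS_20": 0.4,
    # Whi5 / SBF start module
    "k_b_sw": 50.0, "k_u_sw": 0.05, "k_p_whi5": 0.8, "k_dp_whi5": 1.0,
    "e_bck2": 1.0, "e_bS_w5": 1.0,
    # Sic1 chain
    "k_p_s1": 1.2, "e_bM_s1": 0.6, "e_g1_s1": 0.4, "k_dp_s1": 0.4, "k_d_s1p7": 1.0,
    "k_b_s1": 8.0, "k_u_s1": 0.05,
    # Cdh1
    "k_a_h1_14": 2.0, "k_i_h1": 1.0, "e_bS_h1": 0.3,
    # Cdc20 activation
    "k_a_20": 0.2, "k_i_20": 0.1,
    # Mcm1
    "k_a_m1": 0.6, "k_i_m1": 0.1, "k_i_m1_14": 0.5,
    # Swi5
    "k_a_swi5": 2.0, "k_i_swi5": 1.0,
    # Net1 / RENT / Cdc14
    "k_p_net": 0.7, "k_d_t1": 0.3, "k_d_nt": 0.3, "k_b_rent": 20.0,
    "k_u_rent": 1.0,
    # phosphatase Ht1
    "k_s_ht1": 0.01, "k_d_ht1": 0.02,
    # growth
    "mu": BASAL_MU,
}

_DESCRIPTIONS = {
    "k_s_n3": "Cln3 translation rate per mRNA, scales with volume (glucose channel, +)",
    "k_s_mbS": "SBF-driven ClbS transcription rate (glucose channel, -)",
    "k_d_t1": "Ht1-mediated Net1 dephosphorylation, free Net1 (glucose channel, +)",
    "k_d_nt": "Ht1-mediated Net1 dephosphorylation in the RENT complex (glucose channel, +)",
    "k_s_bS": "ClbS translation rate per mRNA",
    "k_s_bM": "ClbM (mitotic cyclin) translation rate per mRNA",
    "mu": "exponential volume growth rate (1/min)",
}


def _rhs(t: float, y: np.ndarray, V: float, p: Mapping[str, float]) -> np.ndarray:
    d = np.zeros_like(y)
    g = _I.__getitem__

    (m_n3, m_bS, m_bM, m_s1, m_20, m_h1, m_swi5, m_whi5, m_net1) = y[:9]
    Cln3, Bck2 = y[g("Cln3")], y[g("Bck2")]
    Whi5, Whi5P = y[g("Whi5")], y[g("Whi5P")]
    SBF, SBFWhi5 = y[g("SBF")], y[g("SBFWhi5")]
    ClbS, ClbM = y[g("ClbS")], y[g("ClbM")]
    S1f = y[_S1F]
    S1s = y[_S1S]
    S1m = y[_S1M]
    Cdh1a, Cdh1P = y[g("Cdh1a")], y[g("Cdh1P")]
    Cdc20i, Cdc20a = y[g("Cdc20i")], y[g("Cdc20a")]
    Mcm1i, Mcm1a = y[g("Mcm1i")], y[g("Mcm1a")]
    Swi5i, Swi5a = y[g("Swi5i")], y[g("Swi5a")]
    Netf = y[_NETF]
    Rent = y[_RENT]
    Cdc14, Ht1 = y[g("Cdc14")], y[g("Ht1")]

    # --- mRNA ---------------------------------------------------------
    d[g("m_n3")] = p["k_s_mn3"] - p["k_d_mn3"] * m_n3
    d[g("m_bS")] = p["k_s_mbS"] * SBF - p["k_d_mbS"] * m_bS
    d[g("m_bM")] = p["k_s_mbMp"] + p["k_s_mbM"] * Mcm1a - p["k_d_mbM"] * m_bM
    d[g("m_s1")] = p["k_s_ms1"] * Swi5a - p["k_d_ms1"] * m_s1
    d[g("m_20")] = p["k_s_m20"] * Mcm1a - p["k_d_m20"] * m_20
    d[g("m_h1")] = p["k_s_mh1"] - p["k_d_m"] * m_h1
    d[g("m_swi5")] = p["k_s_mswi5"] - p["k_d_m"] * m_swi5
    d[g("m_whi5")] = p["k_s_mwhi5"] - p["k_d_m"] * m_whi5
    d[g("m_net1")] = p["k_s_mnet1"] - p["k_d_m"] * m_net1

    # --- size sensors -------------------------------------------------
    d[g("Cln3")] = p["k_s_n3"] * m_n3 * V - p["k_d_n3"] * Cln3
    d[g("Bck2")] = p["k_s_bck2"] * V - p["k_d_bck2"] * Bck2

    # --- Whi5 / SBF start switch -------------------------------------
    kin_g1 = Cln3 + p["e_bck2"] * Bck2 + p["e_bS_w5"] * ClbS
    bind_sw = p["k_b_sw"] * SBF * Whi5
    unbind_sw = p["k_u_sw"] * SBFWhi5
    phos_free = p["k_p_whi5"] * kin_g1 * Whi5
    phos_cplx = p["k_p_whi5"] * kin_g1 * SBFWhi5
    dephos_w5 = p["k_dp_whi5"] * (Ht1 + Cdc14) * Whi5P
    d[g("Whi5")] = (
        p["k_s_whi5"] * m_whi5 - p["k_d_whi5"] * Whi5
        - bind_sw + unbind_sw - phos_free + dephos_w5
    )
    d[g("Whi5P")] = phos_free + phos_cplx - dephos_w5 - p["k_d_whi5"] * Whi5P
    d[g("SBF")] = -bind_sw + unbind_sw + phos_cplx
    d[g("SBFWhi5")] = bind_sw - unbind_sw - phos_cplx

    # --- Sic1 chain and cyclin binding -------------------------------
    kin_s1 = ClbS + p["e_bM_s1"] * ClbM + p["e_g1_s1"] * (Cln3 + Bck2)
    dp_rate = p["k_dp_s1"] * (Cdc14 + Ht1)

    for arr, sl in ((S1f, _S1F), (S1s, _S1S), (S1m, _S1M)):
        fwd = p["k_p_s1"] * kin_s1 * arr          # site i -> i+1
        back = dp_rate * arr                      # site i -> i-1
        dd = np.zeros(N_SIC1)
        dd[1:] += fwd[:-1]
        dd[:-1] -= fwd[:-1]
        dd[:-1] += back[1:]
        dd[1:] -= back[1:]
        dd[-1] -= p["k_d_s1p7"] * arr[-1]         # degraded when fully phosphorylated
        dd -= p["k_d_s1"] * arr                   # basal turnover of every form
        d[sl] += dd

    d[g("Sic1_p0")] += p["k_s_s1"] * m_s1

    bind_s = p["k_b_s1"] * ClbS * S1f
    bind_m = p["k_b_s1"] * ClbM * S1f
    d[_S1F] += -bind_s - bind_m + p["k_u_s1"] * (S1s + S1m)
    d[_S1S] += bind_s - p["k_u_s1"] * S1s
    d[_S1M] += bind_m - p["k_u_s1"] * S1m

    # Cdc20-mediated destruction of complexed cyclin frees Sic1
    apc_s = p["k_d_bS_20"] * Cdc20a
    apc_m = p["k_d_bM_h1"] * Cdh1a + p["k_d_bM_20"] * Cdc20a
    d[_S1S] += -apc_s * S1s
    d[_S1M] += -apc_m * S1m
    d[_S1F] += apc_s * S1s + apc_m * S1m
    # basal cyclin decay inside complexes also frees Sic1
    d[_S1S] += -p["k_d_bS"] * S1s
    d[_S1M] += -p["k_d_bM"] * S1m
    d[_S1F] += p["k_d_bS"] * S1s + p["k_d_bM"] * S1m

    sic_total_s = float(S1s.sum())
    sic_total_m = float(S1m.sum())
    d[g("ClbS")] = (
        p["k_s_bS"] * m_bS - (p["k_d_bS"] + apc_s) * ClbS
        - float(bind_s.sum()) + p["k_u_s1"] * sic_total_s
        + p["k_d_s1p7"] * S1s[-1] + p["k_d_s1"] * sic_total_s
    )
    d[g("ClbM")] = (
        p["k_s_bM"] * m_bM - (p["k_d_bM"] + apc_m) * ClbM
        - float(bind_m.sum()) + p["k_u_s1"] * sic_total_m
        + p["k_d_s1p7"] * S1m[-1] + p["k_d_s1"] * sic_total_m
    )

    # --- Cdh1 ---------------------------------------------------------
    kin_h1 = ClbM + p["e_bS_h1"] * ClbS
    act_h1 = p["k_a_h1_14"] * Cdc14 * Cdh1P
    inact_h1 = p["k_i_h1"] * kin_h1 * Cdh1a
    d[g("Cdh1a")] = p["k_s_h1"] * m_h1 + act_h1 - inact_h1 - p["k_d_h1"] * Cdh1a
    d[g("Cdh1P")] = inact_h1 - act_h1 - p["k_d_h1"] * Cdh1P

    # --- Cdc20 --------------------------------------------------------
    act_20 = p["k_a_20"] * ClbM * Cdc20i
    d[g("Cdc20i")] = (
        p["k_s_20"] * m_20 - act_20 + p["k_i_20"] * Cdc20a - p["k_d_20p"] * Cdc20i
    )
    d[g("Cdc20a")] = act_20 - p["k_i_20"] * Cdc20a - p["k_d_20p"] * Cdc20a

    # --- Mcm1 ---------------------------------------------------------
    act_m1 = p["k_a_m1"] * ClbM * Mcm1i
    inact_m1 = (p["k_i_m1"] + p["k_i_m1_14"] * Cdc14) * Mcm1a
    d[g("Mcm1i")] = 0.002 - act_m1 + inact_m1 - 0.002 * Mcm1i
    d[g("Mcm1a")] = act_m1 - inact_m1 - 0.002 * Mcm1a

    # --- Swi5 ---------------------------------------------------------
    act_sw5 = p["k_a_swi5"] * Cdc14 * Swi5i
    inact_sw5 = p["k_i_swi5"] * ClbM * Swi5a
    d[g("Swi5i")] = (
        p["k_s_swi5"] * m_swi5 - act_sw5 + inact_sw5 - p["k_d_swi5"] * Swi5i
    )
    d[g("Swi5a")] = act_sw5 - inact_sw5 - p["k_d_swi5"] * Swi5a

    # --- Net1 / RENT / Cdc14 -----------------------------------------
    for arr, sl, kdp in ((Netf, _NETF, p["k_d_t1"]), (Rent, _RENT, p["k_d_nt"])):
        fwd = p["k_p_net"] * ClbM * arr
        back = kdp * Ht1 * arr
        dd = np.zeros(N_NET1)
        dd[1:] += fwd[:-1]
        dd[:-1] -= fwd[:-1]
        dd[:-1] += back[1:]
        dd[1:] -= back[1:]
        dd -= p["k_d_net1"] * arr
        d[sl] += dd

    # only dephosphorylated Net1 binds Cdc14; phosphorylated RENT releases it
    bind_r = p["k_b_rent"] * Cdc14 * (1.0 - _W_RENT) * Netf
    unbind_r = p["k_u_rent"] * _W_RENT * Rent
    d[_NETF] += -bind_r + unbind_r
    d[_RENT] += bind_r - unbind_r
    d[g("Net1_p0")] += p["k_s_net1"] * m_net1
    # Cdc14 is a conserved moiety: only exchanged between the free pool
    # and RENT (Net1 decay inside RENT releases it)
    d[g("Cdc14")] = (
        float(unbind_r.sum()) - float(bind_r.sum())
        + p["k_d_net1"] * float(Rent.sum())
    )

    # --- Ht1 ----------------------------------------------------------
    d[g("Ht1")] = p["k_s_ht1"] - p["k_d_ht1"] * Ht1

    return d


def _initial_state() -> np.ndarray:
    """A G1-like newborn state: Sic1 and Whi5 sequestration in place."""
    y = np.zeros(len(STATE_NAMES))
    y[_I["m_n3"]] = 0.5
    y[_I["m_h1"]] = 0.4
    y[_I["m_swi5"]] = 0.4
    y[_I["m_whi5"]] = 0.4
    y[_I["m_net1"]] = 0.4
    y[_I["m_s1"]] = 0.03
    y[_I["Cln3"]] = 0.1
    y[_I["Bck2"]] = 0.1
    y[_I["SBFWhi5"]] = 0.5
    y[_I["Whi5"]] = 0.5
    y[_I["Sic1_p0"]] = 1.0
    y[_I["Cdh1a"]] = 0.8
    y[_I["Mcm1i"]] = 1.0
    y[_I["Swi5i"]] = 0.3
    y[_I["Net1_p0"]] = 0.5
    y[_I["RENT_p0"]] = 0.5
    y[_I["Ht1"]] = 0.5
    return y


def build(mu: float | None = None, overrides: Mapping[str, float] | None = None) -> ModelSpec:
    """Build the Barik-style model at growth rate ``mu`` (default basal)."""
    mu = BASAL_MU if mu is None else mu
    if not mu > 0:
        raise ValueError(f"growth rate mu must be positive, got {mu}")
    params = dict(_BASAL_PARAMS)
    params["mu"] = mu
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise KeyError(f"unknown parameter(s) for model 'barik': {sorted(unknown)}")
        params.update(overrides)

    return ModelSpec(
        name="barik",
        state_names=STATE_NAMES,
        params=params,
        rhs=_rhs,
        budding_rule=EventRule(
            observable=lambda y, V, p: y[_I["ClbS"]],
            threshold=THETA_BUD,
            direction=+1,
            name="budding (free ClbS up)",
        ),
        division_rule=EventRule(
            observable=lambda y, V, p: y[_I["ClbM"]],
            threshold=THETA_DIV,
            direction=-1,
            name="division (free ClbM down)",
        ),
        size_coupling="Cln3 and Bck2 translation scale with volume (size sensors)",
        initial_state=_initial_state(),
        initial_volume=58.29,
        stiff=True,
        param_descriptions=dict(_DESCRIPTIONS),
    )
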