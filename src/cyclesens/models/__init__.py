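"""Registry of growth-coupled cell-cycle oscillator models.

Three models of increasing complexity sit behind one uniform contract
(:class:`~cyclesens.models.spec.ModelSpec`): a minimal two-variable
oscillator (``pfeuty``), a mid-size nine-variable network (``chen``), and a
detailed mass-action model with multisite phosphorylation (``barik``).  The
latter carries the named glucose-signalling parameters used in the
attainable-region case study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .spec import ModelSpec, RegulationChannel

__all__ = [
    "MODEL_NAMES",
    "build_model",
    "validate_model",
    "list_parameters",
    "glucose_channels",
    "ModelSpec",
    "RegulationChannel",
    "ValidationReport",
]

MODEL_NAMES = ("pfeuty", "chen", "barik")


def build_model(
    name: str,
    mu: float | None = None,
    overrides: Mapping[str, float] | None = None,
) -> ModelSpec:
    """Build a registered model at growth rate ``mu`` with parameter overrides."""
    if name == "pfeuty":
        from . import pfeuty

        return pfeuty.build(mu=mu, overrides=overrides)
    if name == "chen":
        from . import chen

        return chen.build(mu=mu, overrides=overrides)
    if name == "barik":
        from . import barik

        return barik.build(mu=mu, overrides=overrides)
    raise KeyError(f"unknown model {name!r}; registered models: {MODEL_NAMES}")


def list_parameters(model: ModelSpec) -> list[tuple[str, float, str]]:
    """Ordered (name, basal value, description) table of all model parameters."""
    return model.parameter_table()


@dataclass
class ValidationReport:
    """Outcome of the structural/behavioural checks on a built model."""

    model: str
    checks: dict[str, bool] = field(default_factory=dict)
    messages: dict[str, str] = field(default_factory=dict)
    metrics: object | None = None

    @property
    def ok(self) -> bool:
        return all(self.checks.values())

    def record(self, name: str, passed: bool, message: str = "") -> None:
        self.checks[name] = bool(passed)
        if message:
            self.messages[name] = message


def validate_model(model: ModelSpec, tol: float = 1e-8, max_gens: int = 200) -> ValidationReport:
    """Check that a model converges to a steady daughter cycle with one
    budding and one division per cycle (in order) and an emergent daughter
    fraction f < 0.5 with a positive G1 duration."""
    from ..simulate import ArrestError, ConvergenceError, find_steady_cycle, simulate_lineage

    report = ValidationReport(model=model.name)
    try:
        metrics, start = find_steady_cycle(model, tol=tol, max_gens=max_gens)
    except (ArrestError, ConvergenceError) as err:
        # classify the failure so callers can see *which* event was missing
        msg = str(err)
        report.record("steady_cycle", False, msg)
        report.record("budding_event", "no budding" not in msg, msg)
        report.record("division_event", "no division" not in msg, msg)
        return report
    report.metrics = metrics
    report.record("steady_cycle", True)
    report.record("budding_event", True)
    report.record("division_event", True)
    report.record(
        "budding_before_division",
        0.0 < metrics.T_G1 < metrics.T_div,
        f"T_G1={metrics.T_G1:.3f}, T_div={metrics.T_div:.3f}",
    )
    report.record("emergent_f_below_half", metrics.f < 0.5, f"f={metrics.f:.4f}")
    # one budding + one division per cycle, strictly interleaved
    traj = simulate_lineage(model, n_generations=3, start=start)
    ok = not traj.arrested
    for i in range(1, traj.n_generations + 1):
        ev = traj.generation_events(i)
        ok = ok and set(ev) == {"birth", "bud", "division"}
        ok = ok and ev["birth"].time < ev["bud"].time < ev["division"].time
    report.record("one_event_pair_per_cycle", ok)
    return report


def glucose_channels(model: ModelSpec) -> list[RegulationChannel]:
    """The three glucose-signalling channels of the detailed model.

    Increasing glucose up-regulates Cln3 translation (``k_s_n3``),
    down-regulates Cln2/ClbS transcription (``k_s_mbS``), and up-regulates
    Net1 dephosphorylation (``k_d_t1`` and ``k_d_nt``, moved proportionally).
    """
    channels = [
        RegulationChannel("cln3_translation", ("k_s_n3",), +1),
        RegulationChannel("clbS_transcription", ("k_s_mbS",), -1),
        RegulationChannel("net1_dephosphorylation", ("k_d_t1", "k_d_nt"), +1),
    ]
    missing = [p for ch in channels for p in ch.parameters if p not in model.params]
    if missing:
        raise ValueError(
            f"model {model.name!r} does not represent the glucose channels "
            f"(missing parameters: {sorted(set(missing))})"
        )
    return channels
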