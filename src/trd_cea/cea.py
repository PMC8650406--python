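"""Incremental cost-effectiveness analysis and the scenario runner.

``incremental`` computes the cost and QALY differences between the ECT
strategy and the esketamine comparator and classifies the result:
dominance (one strategy is cheaper *and* more effective) or an
incremental cost-effectiveness ratio (ICER, GBP per QALY gained),
compared against the UK willingness-to-pay band of 20,000-30,000 GBP
per QALY.

``scenario_catalog`` enumerates the nine one-at-a-time deterministic
sensitivity analyses (productivity doubled/halved; six or twelve ECT
sessions per cycle; esketamine remission raised to 0.5; ECT remission
lowered to 0.5; second-course remission raised to 0.9; five-year
horizon; alternative utilities; open-ended esketamine maintenance; no
discounting), each under the societal and/or healthcare perspective as
published, and ``run_table`` regenerates the full results table for
either model variant.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import pandas as pd

from .engine import ArmResult, ScenarioMods, run_cohort
from .parameters import (
    Arm,
    ModelSettings,
    ParameterBundle,
    Perspective,
    Variant,
    default_parameters,
)

__all__ = [
    "Verdict",
    "CEResult",
    "ScenarioSpec",
    "incremental",
    "scenario_catalog",
    "run_arm",
    "run_pair",
    "run_table",
    "THRESHOLD_LOW",
    "THRESHOLD_HIGH",
]

THRESHOLD_LOW = 20_000.0
THRESHOLD_HIGH = 30_000.0


class Verdict(str, enum.Enum):
    ICER = "ICER"
    ECT_DOMINATES = "ECT_DOMINATES"
    COMPARATOR_DOMINATES = "COMPARATOR_DOMINATES"


@dataclass(frozen=True)
class CEResult:
    cost_ect: float
    qaly_ect: float
    cost_cmp: float
    qaly_cmp: float
    threshold_low: float = THRESHOLD_LOW
    threshold_high: float = THRESHOLD_HIGH

    @property
    def delta_cost(self) -> float:
        return self.cost_ect - self.cost_cmp

    @property
    def delta_qaly(self) -> float:
        return self.qaly_ect - self.qaly_cmp

    @property
    def verdict(self) -> Verdict:
        dc, dq = self.delta_cost, self.delta_qaly
        if dc <= 0 and dq >= 0 and (dc < 0 or dq > 0):
            return Verdict.ECT_DOMINATES
        if dc >= 0 and dq <= 0 and (dc > 0 or dq < 0):
            return Verdict.COMPARATOR_DOMINATES
        return Verdict.ICER

    @property
    def icer(self) -> float | None:
        """GBP per QALY; defined only when both deltas share a sign and
        the QALY delta is non-zero (otherwise dominance applies)."""
        if self.verdict is not Verdict.ICER or self.delta_qaly == 0:
            return None
        return self.delta_cost / self.delta_qaly

    def cost_effective(self, threshold: float) -> bool:
        """Is ECT cost-effective against the comparator at a
        willingness-to-pay threshold?"""
        if self.verdict is Verdict.ECT_DOMINATES:
            return True
        if self.verdict is Verdict.COMPARATOR_DOMINATES:
            return False
        assert self.icer is not None
        # more costly & more effective: cost-effective below the threshold;
        # cheaper & less effective: cost-effective if savings per QALY
        # forgone exceed the threshold
        if self.delta_qaly > 0:
            return self.icer < threshold
        return self.icer > threshold


def incremental(ect: ArmResult, cmp: ArmResult) -> CEResult:
    """Incremental comparison of two arm runs with identical settings
    apart from the treatment arm."""
    s_e = dataclasses.replace(ect.settings, arm=Arm.ECT)
    s_c = dataclasses.replace(cmp.settings, arm=Arm.ECT)
    if s_e != s_c:
        raise ValueError("arm results were produced under different settings")
    return CEResult(
        cost_ect=ect.total_cost,
        qaly_ect=ect.total_qaly,
        cost_cmp=cmp.total_cost,
        qaly_cmp=cmp.total_qaly,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    description: str
    perspective: Perspective
    mods_ect: ScenarioMods = field(default_factory=ScenarioMods)
    mods_esk: ScenarioMods = field(default_factory=ScenarioMods)


def _scenario7_mods(
    variant: Variant, include_ect_b: bool
) -> tuple[ScenarioMods, ScenarioMods]:
    """Alternative utilities: 0.3/yr while depressed on ECT (states A and
    C of the ECT arm) and 0.85/yr for remission on an ordinary
    antidepressant after esketamine or standard treatment (esketamine
    tunnel and F, plus state E in both arms).

    Remission maintained by the index treatment itself (ECT-arm B, the
    M-ECT tunnel) keeps the base utility by default; ``include_ect_b``
    extends 0.85 to the ECT-arm remission states as well.
    """
    ect_states = {"A": 0.3, "C": 0.3, "E": 0.85}
    if include_ect_b:
        if variant is Variant.MAIN:
            ect_states["B"] = 0.85
        else:
            ect_states["B1"] = 0.85
            ect_states["B2plus"] = 0.85
    esk_states = {f"B{i}": 0.85 for i in range(1, 7)}
    esk_states.update({"F": 0.85, "E": 0.85})
    return (
        ScenarioMods(state_utility_annual=ect_states),
        ScenarioMods(state_utility_annual=esk_states),
    )


def scenario_catalog(
    variant: Variant, scenario7_includes_ect_b: bool = False
) -> list[ScenarioSpec]:
    """The published deterministic sensitivity analyses, one
    ``ScenarioSpec`` per printed table row."""
    soc, hc = Perspective.SOCIETAL, Perspective.HEALTHCARE
    s7_ect, s7_esk = _scenario7_mods(variant, scenario7_includes_ect_b)
    rows: list[ScenarioSpec] = []

    def add(sid: str, desc: str, persp: Perspective, ect: ScenarioMods, esk: ScenarioMods) -> None:
        rows.append(ScenarioSpec(sid, desc, persp, ect, esk))

    both = lambda **kw: (ScenarioMods(**kw), ScenarioMods(**kw))  # noqa: E731

    e, k = both(productivity_multiplier=2.0)
    add("1a", "Doubling the productivity loss", soc, e, k)
    e, k = both(productivity_multiplier=0.5)
    add("1b", "Halving the productivity loss", soc, e, k)

    for sid, n, persp in (("2a", 6, soc), ("2b", 6, hc), ("2c", 12, soc), ("2d", 12, hc)):
        add(
            sid,
            f"ECT {n} times per cycle - {persp.value.lower()}",
            persp,
            ScenarioMods(ect_sessions=n),
            ScenarioMods(),
        )

    esk_05 = ScenarioMods(transition_overrides={"tpA2B_esk": 0.5, "tpC2B_esk": 0.5})
    add("3a", "Esketamine remission rate 0.5 - societal", soc, ScenarioMods(), esk_05)
    add("3b", "Esketamine remission rate 0.5 - healthcare", hc, ScenarioMods(), esk_05)

    ect_05 = ScenarioMods(transition_overrides={"tpA2B_ect": 0.5, "tpC2B_ect": 0.5})
    add("4a", "ECT remission rate 0.5 - societal", soc, ect_05, ScenarioMods())
    add("4b", "ECT remission rate 0.5 - healthcare", hc, ect_05, ScenarioMods())

    second_ect = ScenarioMods(transition_overrides={"tpC2B_ect": 0.9})
    second_esk = ScenarioMods(transition_overrides={"tpC2B_esk": 0.9})
    add("5a", "Second-course remission rate 0.9 - societal", soc, second_ect, second_esk)
    add("5b", "Second-course remission rate 0.9 - healthcare", hc, second_ect, second_esk)

    e, k = both(horizon_years=5)
    add("6a", "Five-year time horizon - societal", soc, e, k)
    e, k = both(horizon_years=5)
    add("6b", "Five-year time horizon - healthcare", hc, e, k)

    add("7a", "Utilities 0.3 during ECT / 0.85 post-esketamine+AD remission - societal",
        soc, s7_ect, s7_esk)
    add("7b", "Utilities 0.3 during ECT / 0.85 post-esketamine+AD remission - healthcare",
        hc, s7_ect, s7_esk)

    indef = ScenarioMods(esk_maintenance_indefinite=True)
    add("8a", "Esketamine for as long as in remission - societal", soc, ScenarioMods(), indef)
    add("8b", "Esketamine for as long as in remission - healthcare", hc, ScenarioMods(), indef)

    e, k = both(annual_discount_rate=0.0)
    add("9a", "No discounting - societal", soc, e, k)
    e, k = both(annual_discount_rate=0.0)
    add("9b", "No discounting - healthcare", hc, e, k)
    return rows


def run_arm(
    arm: Arm,
    variant: Variant,
    perspective: Perspective,
    bundle: ParameterBundle | None = None,
    mods: ScenarioMods | None = None,
    settings: ModelSettings | None = None,
) -> ArmResult:
    bundle = bundle or default_parameters()
    settings = settings or bundle.settings
    settings = dataclasses.replace(
        settings, arm=arm, variant=variant, perspective=perspective
    )
    return run_cohort(settings, bundle, mods)


def run_pair(
    variant: Variant,
    perspective: Perspective,
    bundle: ParameterBundle | None = None,
    mods_ect: ScenarioMods | None = None,
    mods_esk: ScenarioMods | None = None,
) -> tuple[ArmResult, ArmResult, CEResult]:
    ect = run_arm(Arm.ECT, variant, perspective, bundle, mods_ect)
    esk = run_arm(Arm.ESKETAMINE, variant, perspective, bundle, mods_esk)
    return ect, esk, incremental(ect, esk)


def run_table(
    variant: Variant,
    bundle: ParameterBundle | None = None,
    scenario7_includes_ect_b: bool = False,
) -> pd.DataFrame:
    """Regenerate the full published results table (base case plus all
    sensitivity rows) for one model variant."""
    bundle = bundle or default_parameters()
    rows = []

    def record(sid: str, desc: str, persp: Perspective, ce: CEResult) -> None:
        rows.append(
            {
                "row": sid,
                "description": desc,
                "perspective": persp.value,
                "cost_ect": ce.cost_ect,
                "qaly_ect": ce.qaly_ect,
                "cost_esk": ce.cost_cmp,
                "qaly_esk": ce.qaly_cmp,
                "delta_cost": ce.delta_cost,
                "delta_qaly": ce.delta_qaly,
                "icer": ce.icer,
                "verdict": ce.verdict.value,
                "cost_effective_20k": ce.cost_effective(THRESHOLD_LOW),
                "cost_effective_30k": ce.cost_effective(THRESHOLD_HIGH),
            }
        )

    for persp in (Perspective.SOCIETAL, Perspective.HEALTHCARE):
        _, _, ce = run_pair(variant, persp, bundle)
        record("base", f"Base case - {persp.value.lower()}", persp, ce)
    for spec in scenario_catalog(variant, scenario7_includes_ect_b):
        _, _, ce = run_pair(variant, spec.perspective, bundle, spec.mods_ect, spec.mods_esk)
        record(spec.id, spec.description, spec.perspective, ce)
    return pd.DataFrame(rows)
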