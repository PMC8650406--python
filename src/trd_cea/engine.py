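"""Discrete-time Markov cohort engine over the expanded state space.

Health states: A (depression, first course of the index treatment),
B (remission on the index treatment's follow-up schedule; expanded into
tunnel phases where costs depend on time since entry), C (depression,
re-treatment after relapse from B/F), D (depression on standard
treatment after the index treatment failed), E (remission on standard
treatment reached from D), F (remission on standard treatment after
completing the six-month esketamine maintenance schedule; esketamine
arm only) and G (dead, absorbing).

A and C are single-cycle treatment states: a course of ECT (eight
sessions) or the esketamine induction fits inside one 30-day cycle, so
their whole occupancy resolves each cycle into remission, death or
(residually) D.  All exit probabilities of a state are applied
simultaneously as one stochastic row; the residual mass defines the
remaining transition.  Mortality is the excess-risk-adjusted depression
mortality in A/C/D and the age-banded life-table mortality in the
remission states.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import CostModifiers, state_cycle_cost
from .parameters import (
    Arm,
    ModelSettings,
    ParameterBundle,
    TransitionInputs,
    Variant,
    DiscountConvention,
)

__all__ = [
    "StateDef",
    "ScenarioMods",
    "CohortModel",
    "ArmResult",
    "state_space",
    "build_transition_row",
    "build_model",
    "discount_factor",
    "run_cohort",
]

MASS_TOL = 1e-9


@dataclass(frozen=True)
class StateDef:
    name: str
    cost_key: str | None  # None for the dead state
    utility_class: str  # DEPRESSION | REMISSION | DEAD


@dataclass(frozen=True)
class ScenarioMods:
    """One-at-a-time deviations from the base case.

    ``transition_overrides`` maps ``TransitionInputs`` field names to new
    per-cycle probabilities; ``state_utility_annual`` maps state names to
    replacement annual utilities.  ``esk_maintenance_indefinite`` keeps
    the esketamine maintenance schedule running (at the months-2-to-5
    dose and cost) for as long as the individual stays in remission, so
    state F becomes unreachable.
    """

    transition_overrides: dict[str, float] = field(default_factory=dict)
    state_utility_annual: dict[str, float] = field(default_factory=dict)
    productivity_multiplier: float = 1.0
    ect_sessions: int = 8
    horizon_years: int | None = None
    annual_discount_rate: float | None = None
    esk_maintenance_indefinite: bool = False

    def cost_modifiers(self) -> CostModifiers:
        return CostModifiers(
            productivity_multiplier=self.productivity_multiplier,
            ect_sessions=self.ect_sessions,
        )


def state_space(arm: Arm, variant: Variant, esk_indefinite: bool = False) -> list[StateDef]:
    """The realised expanded state set for an arm/variant."""
    dead = StateDef("G", None, "DEAD")
    common_tail = [
        StateDef("D", "any/D", "DEPRESSION"),
        StateDef("E", "any/EF", "REMISSION"),
    ]
    if arm is Arm.ECT:
        head = [StateDef("A", "ect/AC", "DEPRESSION")]
        if variant is Variant.MAIN:
            b_states = [StateDef("B", "ect/B_standard", "REMISSION")]
        else:
            b_states = [
                StateDef("B1", "ect/B_mect_month1", "REMISSION"),
                StateDef("B2plus", "ect/B_mect_ongoing", "REMISSION"),
            ]
        mid = [StateDef("C", "ect/AC", "DEPRESSION")]
        return head + b_states + mid + common_tail + [dead]
    # esketamine arm (identical under both model variants)
    head = [StateDef("A", "esk/AC", "DEPRESSION")]
    if esk_indefinite:
        b_states = [
            StateDef("B1", "esk/B_month1", "REMISSION"),
            StateDef("B2plus", "esk/B_month2to5", "REMISSION"),
        ]
        f_states: list[StateDef] = []
    else:
        phase_keys = ["esk/B_month1"] + ["esk/B_month2to5"] * 4 + ["esk/B_month6"]
        b_states = [StateDef(f"B{i+1}", phase_keys[i], "REMISSION") for i in range(6)]
        f_states = [StateDef("F", "any/EF", "REMISSION")]
    mid = [StateDef("C", "esk/AC", "DEPRESSION")]
    return head + b_states + mid + common_tail + f_states + [dead]


def build_transition_row(
    state: str,
    arm: Arm,
    variant: Variant,
    remission_mortality: float,
    tr: TransitionInputs,
    esk_indefinite: bool = False,
) -> dict[str, float]:
    """Named transition probabilities out of one state; the residual mass
    is assigned explicitly so the row sums to 1."""
    m = remission_mortality
    if arm is Arm.ECT:
        remit_a, remit_c = tr.tpA2B_ect, tr.tpC2B_ect
        b_first = "B" if variant is Variant.MAIN else "B1"
        relapse = tr.tpB2C_ect if variant is Variant.MAIN else tr.tpB2C_mect
    else:
        remit_a, remit_c = tr.tpA2B_esk, tr.tpC2B_esk
        b_first = "B1"
        relapse = tr.tpB2C_esk

    def residual(row: dict[str, float], to: str) -> dict[str, float]:
        named = sum(row.values())
        if named > 1.0 + MASS_TOL:
            raise ValueError(
                f"exit probabilities from state {state} sum to {named:.6f} > 1"
            )
        row[to] = max(0.0, 1.0 - named)
        return row

    if state == "G":
        return {"G": 1.0}
    if state == "A":
        return residual({b_first: remit_a, "G": tr.tpDepression2Death}, "D")
    if state == "C":
        return residual({b_first: remit_c, "G": tr.tpDepression2Death}, "D")
    if state == "D":
        return residual({"E": tr.tpD2E, "G": tr.tpDepression2Death}, "D")
    if state == "E":
        return residual({"D": tr.tpE2D, "G": m}, "E")
    if state == "F":
        # relapse after the maintenance schedule ended: re-treatment, at the
        # standard-treatment relapse probability
        return residual({"C": tr.tpE2D, "G": m}, "F")
    if state == "B":  # ECT main model: remission on standard treatment
        return residual({"C": relapse, "G": m}, "B")
    if state == "B2plus":  # open-ended maintenance phase (M-ECT, or scenario-8 esketamine)
        return residual({"C": relapse, "G": m}, "B2plus")
    if state == "B1" and (arm is Arm.ECT or esk_indefinite):
        return residual({"C": relapse, "G": m}, "B2plus")
    if state.startswith("B"):  # esketamine monthly tunnel B1..B6
        month = int(state[1:])
        nxt = f"B{month + 1}" if month < 6 else "F"
        return residual({"C": relapse, "G": m}, nxt)
    raise ValueError(f"unknown state: {state}")


def discount_factor(
    cycle_index: int, settings: ModelSettings, annual_rate: float | None = None
) -> float:
    """Discount factor applied to flows accrued in a given cycle."""
    d = settings.annual_discount_rate if annual_rate is None else annual_rate
    if d == 0.0:
        return 1.0
    if settings.discount_convention is DiscountConvention.ANNUAL_STEP:
        years = cycle_index // settings.cycles_per_year
    else:
        years = cycle_index / settings.cycles_per_year
    return float((1.0 + d) ** (-years))


@dataclass
class CohortModel:
    """Precomputed arrays shared by the cohort recursion and the
    individual-level microsimulation, so both use identical accounting."""

    settings: ModelSettings
    states: list[StateDef]
    horizon_cycles: int
    band_matrices: dict[int, np.ndarray]  # mortality band lower bound -> row-stochastic matrix
    band_for_cycle: np.ndarray  # cycle -> band lower bound
    cost_lt65: np.ndarray
    cost_ge65: np.ndarray
    lt65_for_cycle: np.ndarray  # bool per cycle
    utilities: np.ndarray  # per-cycle utility accrual per state
    dfs: np.ndarray  # discount factor per cycle

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.states]

    def matrix_at(self, cycle: int) -> np.ndarray:
        return self.band_matrices[int(self.band_for_cycle[cycle])]

    def costs_at(self, cycle: int) -> np.ndarray:
        return self.cost_lt65 if self.lt65_for_cycle[cycle] else self.cost_ge65


def build_model(
    settings: ModelSettings,
    bundle: ParameterBundle,
    mods: ScenarioMods | None = None,
) -> CohortModel:
    mods = mods or ScenarioMods()
    tr = bundle.transitions
    if mods.transition_overrides:
        unknown = set(mods.transition_overrides) - {
            f.name for f in dataclasses.fields(TransitionInputs)
        }
        if unknown:
            raise ValueError(f"unknown transition overrides: {sorted(unknown)}")
        tr = dataclasses.replace(tr, **mods.transition_overrides)

    states = state_space(settings.arm, settings.variant, mods.esk_maintenance_indefinite)
    names = [s.name for s in states]
    index = {n: i for i, n in enumerate(names)}
    horizon_years = (
        mods.horizon_years if mods.horizon_years is not None else settings.horizon_years
    )
    horizon = horizon_years * settings.cycles_per_year

    ages = settings.start_age + np.arange(horizon) // settings.cycles_per_year
    bands = np.clip(5 * (ages // 5), 45, 75)
    band_matrices: dict[int, np.ndarray] = {}
    for band in np.unique(bands):
        m = tr.remission_mortality[int(band)]
        mat = np.zeros((len(states), len(states)))
        for s in states:
            row = build_transition_row(
                s.name, settings.arm, settings.variant, m, tr, mods.esk_maintenance_indefinite
            )
            for target, p in row.items():
                mat[index[s.name], index[target]] = p
        band_matrices[int(band)] = mat

    cmods = mods.cost_modifiers()
    young = bundle.wages.retirement_age - 1
    old = bundle.wages.retirement_age
    cost_lt65 = np.array(
        [
            0.0 if s.cost_key is None
            else state_cycle_cost(s.cost_key, young, settings.perspective, bundle, cmods)
            for s in states
        ]
    )
    cost_ge65 = np.array(
        [
            0.0 if s.cost_key is None
            else state_cycle_cost(s.cost_key, old, settings.perspective, bundle, cmods)
            for s in states
        ]
    )

    u_rem, u_dep = bundle.utilities.per_cycle(settings.cycles_per_year)
    base_util = {"REMISSION": u_rem, "DEPRESSION": u_dep, "DEAD": 0.0}
    utilities = np.array(
        [
            mods.state_utility_annual[s.name] / settings.cycles_per_year
            if s.name in mods.state_utility_annual
            else base_util[s.utility_class]
            for s in states
        ]
    )

    dfs = np.array(
        [discount_factor(c, settings, mods.annual_discount_rate) for c in range(horizon)]
    )
    return CohortModel(
        settings=settings,
        states=states,
        horizon_cycles=horizon,
        band_matrices=band_matrices,
        band_for_cycle=bands,
        cost_lt65=cost_lt65,
        cost_ge65=cost_ge65,
        lt65_for_cycle=ages < bundle.wages.retirement_age,
        utilities=utilities,
        dfs=dfs,
    )


@dataclass
class ArmResult:
    total_cost: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    trace: pd.DataFrame
    settings: ModelSettings

    def totals(self) -> dict[str, float]:
        return {
            "cost": self.total_cost,
            "qaly": self.total_qaly,
            "undiscounted_cost": self.undiscounted_cost,
            "undiscounted_qaly": self.undiscounted_qaly,
        }


def run_cohort(
    settings: ModelSettings,
    bundle: ParameterBundle,
    mods: ScenarioMods | None = None,
) -> ArmResult:
    """Run the cohort recursion: the whole cohort starts depressed in
    state A; each cycle accrues state costs and utilities (discounted)
    and then redistributes occupancy through the transition matrix."""
    model = build_model(settings, bundle, mods)
    n = len(model.states)
    horizon = model.horizon_cycles

    occ = np.zeros((horizon + 1, n))
    occ[0, model.names.index("A")] = 1.0
    for c in range(horizon):
        occ[c + 1] = occ[c] @ model.matrix_at(c)

    weights = occ[:horizon]
    if settings.half_cycle_correction:
        weights = 0.5 * (occ[:horizon] + occ[1 : horizon + 1])

    cost_vec = np.where(
        model.lt65_for_cycle[:, None], model.cost_lt65[None, :], model.cost_ge65[None, :]
    )
    cycle_cost = (weights * cost_vec).sum(axis=1)
    cycle_qaly = weights @ model.utilities

    trace = pd.DataFrame(occ[:horizon], columns=model.names)
    trace.insert(0, "cycle", np.arange(horizon))
    trace.insert(
        1, "age", settings.start_age + np.arange(horizon) // settings.cycles_per_year
    )
    trace["cycle_cost"] = cycle_cost
    trace["cycle_qaly"] = cycle_qaly
    trace["discount_factor"] = model.dfs
    trace["disc_cost"] = cycle_cost * model.dfs
    trace["disc_qaly"] = cycle_qaly * model.dfs

    return ArmResult(
        total_cost=float(trace["disc_cost"].sum()),
        total_qaly=float(trace["disc_qaly"].sum()),
        undiscounted_cost=float(cycle_cost.sum()),
        undiscounted_qaly=float(cycle_qaly.sum()),
        trace=trace,
        settings=settings,
    )
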