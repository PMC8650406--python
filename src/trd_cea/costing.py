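"""Per-state per-cycle costs: productivity loss, perspective switch, and
the direct / informal-care / travel decomposition.

The published input table prints, for every state and treatment phase,
the societal per-cycle cost for ages <65 and >=65.  The difference
between the two columns is the productivity loss, which this module
re-derives from the wage formula (human-capital approach with the
general wage rate): the monthly value of lost work is wage plus the
payroll tax due on it, weighted by the employment mix of each health
state.  After the retirement age of 65 no productivity loss accrues.

The >=65 column is therefore "societal minus productivity" and is
decomposed as direct healthcare + informal care + travel.  The source
tables print only the totals, so the split is an explicit calibration:
travel is the per-visit cap times the number of clinic visits each
phase's schedule implies, informal care is a property of the health
state (a fixed amount per depressed cycle, none in remission), and the
direct healthcare cost is the remainder.  A per-state ``direct_override``
inverts this (informal care becomes the residual, which must be
non-negative).  Only the healthcare perspective depends on this split;
societal totals are the printed values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .parameters import (
    EmploymentInputs,
    ParameterBundle,
    Perspective,
    StateCostRow,
    UnitCosts,
    WageInputs,
)

__all__ = [
    "CostComponents",
    "CostModifiers",
    "payroll_tax",
    "productivity_loss",
    "calibrate_direct_costs",
    "state_cycle_cost",
    "ect_frequency_delta",
    "cost_table_frame",
]

DEPRESSION_COST_KEYS = {"ect/AC", "esk/AC", "any/D"}


@dataclass(frozen=True)
class CostComponents:
    """GBP per cycle, one state/phase and age band."""

    direct_healthcare: float
    productivity_loss: float
    informal_care: float
    travel: float

    @property
    def societal(self) -> float:
        return self.direct_healthcare + self.productivity_loss + self.informal_care + self.travel

    @property
    def healthcare(self) -> float:
        return self.direct_healthcare


@dataclass(frozen=True)
class CostModifiers:
    """Scenario hooks that act on the cost side of the model."""

    productivity_multiplier: float = 1.0
    ect_sessions: int = 8  # sessions per treatment cycle in states A/C


def payroll_tax(gross_monthly: float, wages: WageInputs | None = None) -> float:
    """Payroll tax on one month of gross income (banded flat rate)."""
    w = wages or WageInputs()
    if gross_monthly < 0:
        raise ValueError("gross income must be non-negative")
    taxable = max(0.0, min(gross_monthly, w.payroll_band_high) - w.payroll_band_low)
    return w.payroll_tax_rate * taxable


def productivity_loss(
    state_class: str,
    age: int,
    wages: WageInputs,
    employment: EmploymentInputs,
) -> float:
    """Lost production per cycle for a health-state class at a given age.

    ``state_class`` is ``"DEPRESSION"`` or ``"REMISSION"``.  In depression
    the unemployed fraction loses a full-time wage's value and the
    part-time fraction the difference between full- and part-time value;
    in remission only the unemployed fraction contributes.  Zero from the
    retirement age onward.
    """
    if age >= wages.retirement_age:
        return 0.0
    v_ft = wages.fulltime_wage + payroll_tax(wages.fulltime_wage, wages)
    v_pt = wages.parttime_wage + payroll_tax(wages.parttime_wage, wages)
    if state_class == "DEPRESSION":
        return (
            employment.depression_unemployed * v_ft
            + employment.depression_parttime * (v_ft - v_pt)
        )
    if state_class == "REMISSION":
        return employment.remission_unemployed * v_ft
    raise ValueError(f"unknown state class: {state_class}")


def _direct_estimate(key: str, u: UnitCosts) -> float:
    """Direct healthcare cost per cycle assembled from unit costs."""
    gp_ad = u.gp_visit + u.antidepressant_cycle
    per_mg = u.esketamine_per_mg
    if key == "ect/AC":
        return 8 * u.ect_session + 2 * u.psychiatrist_visit + gp_ad + u.trd_residual_care_cycle
    if key == "esk/AC":
        return (
            u.esk_mg_induction * per_mg
            + 8 * u.nurse_administration
            + 2 * u.psychiatrist_visit
            + gp_ad
            + u.trd_residual_care_cycle
        )
    if key == "ect/B_mect_month1":
        return 4 * u.ect_session + gp_ad
    if key == "ect/B_mect_ongoing":
        return 2 * u.ect_session + gp_ad
    if key == "esk/B_month1":
        return u.esk_mg_maintenance_month1 * per_mg + 4 * u.nurse_administration + gp_ad
    if key == "esk/B_month2to5":
        return u.esk_mg_maintenance_biweekly * per_mg + 2 * u.nurse_administration + gp_ad
    if key == "esk/B_month6":
        return (
            u.esk_mg_maintenance_biweekly * per_mg
            + 2 * u.nurse_administration
            + u.psychiatrist_visit
            + gp_ad
        )
    if key == "any/D":
        return gp_ad + u.trd_residual_care_cycle
    if key in ("ect/B_standard", "any/EF"):
        return gp_ad
    raise KeyError(f"unknown state-cost key: {key}")


def calibrate_direct_costs(bundle: ParameterBundle) -> dict[str, CostComponents]:
    """Decompose every >=65 societal total into direct + informal + travel.

    Returns the age >=65 components (productivity 0).  By default,
    informal care is the per-cycle amount for the state's class
    (depression or remission) and the direct healthcare cost is the
    remainder after informal care and travel.  A row with a
    ``direct_override`` pins the direct cost instead, making informal
    care the residual.  A negative residual in either direction
    (inconsistent overrides) raises ``ValueError``.

    The resulting direct costs agree with bottom-up assembly from unit
    costs (``_direct_estimate``) to within a few percent; the residual
    form is used so the decomposition sums exactly to the printed
    column.
    """
    out: dict[str, CostComponents] = {}
    u = bundle.unit_costs
    for key, row in bundle.state_costs.items():
        travel = row.travel_visits * u.travel_per_visit
        if row.direct_override is not None:
            direct = row.direct_override
            informal = row.societal_ge65 - direct - travel
        else:
            informal = (
                u.informal_care_depression_cycle
                if key in DEPRESSION_COST_KEYS
                else u.informal_care_remission_cycle
            )
            direct = row.societal_ge65 - informal - travel
        if informal < 0 or direct < 0:
            raise ValueError(
                f"state_costs[{key}]: informal care ({informal:.2f}) + travel "
                f"({travel:.2f}) + direct ({direct:.2f}) inconsistent with the "
                f">=65 societal total ({row.societal_ge65:.2f})"
            )
        out[key] = CostComponents(
            direct_healthcare=direct,
            productivity_loss=0.0,
            informal_care=informal,
            travel=travel,
        )
    return out


def _with_ect_sessions(
    key: str, row: StateCostRow, comp: CostComponents, u: UnitCosts, n_sessions: int
) -> tuple[StateCostRow, CostComponents]:
    """Apply the ECT-frequency scenario to the treatment states A/C."""
    if key != "ect/AC" or n_sessions == 8:
        return row, comp
    d_hc = ect_frequency_delta(n_sessions, Perspective.HEALTHCARE, u)
    d_soc = ect_frequency_delta(n_sessions, Perspective.SOCIETAL, u)
    row = replace(
        row,
        societal_lt65=row.societal_lt65 + d_soc,
        societal_ge65=row.societal_ge65 + d_soc,
    )
    comp = CostComponents(
        direct_healthcare=comp.direct_healthcare + d_hc,
        productivity_loss=comp.productivity_loss,
        informal_care=comp.informal_care,
        travel=comp.travel + (d_soc - d_hc),
    )
    return row, comp


def ect_frequency_delta(
    n_sessions: int, perspective: Perspective, unit_costs: UnitCosts | None = None
) -> float:
    """Per-cycle cost change in states A/C when the ECT course has
    ``n_sessions`` instead of the base eight.  Travel accompanies each
    session under the societal perspective only."""
    if n_sessions < 1:
        raise ValueError("need at least one ECT session")
    u = unit_costs or UnitCosts()
    per_session = u.ect_session
    if perspective is Perspective.SOCIETAL:
        per_session += u.travel_per_visit
    return (n_sessions - 8) * per_session


def state_cycle_cost(
    key: str,
    age: int,
    perspective: Perspective,
    bundle: ParameterBundle,
    mods: CostModifiers | None = None,
) -> float:
    """Cost per cycle of one state/phase at a given age and perspective.

    Societal <65 = printed total with the productivity component scaled
    by the scenario multiplier; societal >=65 = printed >=65 total;
    healthcare = calibrated direct component only.  The dead state is not
    a key here — it costs zero.
    """
    mods = mods or CostModifiers()
    row = bundle.state_costs[key]
    components = calibrate_direct_costs(bundle)[key]
    row, components = _with_ect_sessions(key, row, components, bundle.unit_costs, mods.ect_sessions)
    if perspective is Perspective.HEALTHCARE:
        return components.healthcare
    if age >= bundle.wages.retirement_age:
        return row.societal_ge65
    prod = row.societal_lt65 - row.societal_ge65
    return row.societal_ge65 + prod * mods.productivity_multiplier


def cost_table_frame(bundle: ParameterBundle):
    """Cost components as a tidy DataFrame (state key x age band x component)."""
    import pandas as pd

    comps = calibrate_direct_costs(bundle)
    rows = []
    for key, row in bundle.state_costs.items():
        c = comps[key]
        prod = row.societal_lt65 - row.societal_ge65
        for band, productivity in (("<65", prod), (">=65", 0.0)):
            rows.append(
                {
                    "state": key,
                    "age_band": band,
                    "direct_healthcare": c.direct_healthcare,
                    "productivity_loss": productivity,
                    "informal_care": c.informal_care,
                    "travel": c.travel,
                    "societal_total": c.direct_healthcare + productivity + c.informal_care + c.travel,
                }
            )
    return pd.DataFrame(rows)
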