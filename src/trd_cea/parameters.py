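"""Typed model parameters with published-table defaults and YAML config I/O.

Every input of the cost-utility model lives here: per-cycle transition
probabilities, age-banded remission mortality, annual utilities, wages
and employment fractions for the productivity-loss formula, unit costs,
and the per-state per-cycle societal cost table (GBP 2019) split by age
band (<65 / >=65, the retirement boundary).

``default_parameters()`` returns the complete published parameterisation;
``load_config``/``save_config`` round-trip the bundle through a flat YAML
file so any value can be overridden for sensitivity work.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "Arm",
    "Variant",
    "Perspective",
    "DiscountConvention",
    "ModelSettings",
    "TransitionInputs",
    "UtilityInputs",
    "WageInputs",
    "EmploymentInputs",
    "UnitCosts",
    "StateCostRow",
    "ParameterBundle",
    "default_parameters",
    "validate",
    "load_config",
    "save_config",
    "PACKAGED_CONFIG",
]

PACKAGED_CONFIG = Path(__file__).parent / "data" / "table1.yaml"


class Arm(str, enum.Enum):
    ECT = "ECT"
    ESKETAMINE = "ESKETAMINE"


class Variant(str, enum.Enum):
    """MAIN: no maintenance ECT. MAINTENANCE: remitters on ECT receive M-ECT."""

    MAIN = "MAIN"
    MAINTENANCE = "MAINTENANCE"


class Perspective(str, enum.Enum):
    SOCIETAL = "SOCIETAL"
    HEALTHCARE = "HEALTHCARE"


class DiscountConvention(str, enum.Enum):
    """How the annual discount rate maps onto 30-day cycles.

    PER_CYCLE_CONTINUOUS: factor (1+d)^(-cycle/12) — smooth compounding.
    ANNUAL_STEP: factor (1+d)^(-floor(cycle/12)) — spreadsheet-style yearly steps.
    """

    PER_CYCLE_CONTINUOUS = "PER_CYCLE_CONTINUOUS"
    ANNUAL_STEP = "ANNUAL_STEP"


@dataclass
class ModelSettings:
    arm: Arm = Arm.ECT
    variant: Variant = Variant.MAIN
    perspective: Perspective = Perspective.SOCIETAL
    start_age: int = 45
    horizon_years: int = 35
    cycle_length_days: float = 30.0
    cycles_per_year: int = 12
    annual_discount_rate: float = 0.035
    discount_convention: DiscountConvention = DiscountConvention.PER_CYCLE_CONTINUOUS
    half_cycle_correction: bool = False

    @property
    def horizon_cycles(self) -> int:
        return self.horizon_years * self.cycles_per_year


@dataclass
class TransitionInputs:
    """Per-cycle (30-day) transition probabilities.

    ``tpC2B_*`` are stored separately from ``tpA2B_*`` (they are equal by
    default) so the second-line remission rate can be varied on its own.
    ``remission_mortality`` maps five-year age-band lower bounds to the
    per-cycle probability of death while in remission (life-table).
    """

    tpA2B_ect: float = 0.696
    tpC2B_ect: float = 0.696
    tpB2C_ect: float = 0.108
    tpB2C_mect: float = 0.0300
    tpA2B_esk: float = 0.392
    tpC2B_esk: float = 0.392
    tpB2C_esk: float = 0.0724
    tpDepression2Death: float = 0.00304  # tpA2G = tpC2G = tpD2G
    tpD2E: float = 0.107
    tpE2D: float = 0.232
    remission_mortality: dict[int, float] = field(
        default_factory=lambda: {
            45: 0.000180,
            50: 0.000265,
            55: 0.000407,
            60: 0.000646,
            65: 0.00100,
            70: 0.00163,
            75: 0.00285,
        }
    )

    def mortality_at_age(self, age: int) -> float:
        """Remission (life-table) per-cycle mortality for a given age.

        Ages beyond the last tabulated band (75-79) are clamped to that
        band; the default horizon ends at age 80 so the clamp is only a
        guard for extended horizons.
        """
        band = max(45, min(75, 5 * (age // 5)))
        return self.remission_mortality[band]


@dataclass
class UtilityInputs:
    """Annual utilities; per-cycle values are annual / cycles-per-year.

    The published input table displays the per-cycle utilities rounded to
    two decimals (0.07 / 0.05); those displayed values are available via
    ``use_rounded_cycle_values`` but are not the default because
    0.07 x 12 = 0.84 != 0.81.
    """

    annual_remission: float = 0.81
    annual_depression: float = 0.57
    use_rounded_cycle_values: bool = False
    rounded_cycle_remission: float = 0.07
    rounded_cycle_depression: float = 0.05

    def per_cycle(self, cycles_per_year: int = 12) -> tuple[float, float]:
        """(remission, depression) utility accrued per cycle."""
        if self.use_rounded_cycle_values:
            return self.rounded_cycle_remission, self.rounded_cycle_depression
        return (
            self.annual_remission / cycles_per_year,
            self.annual_depression / cycles_per_year,
        )


@dataclass
class WageInputs:
    fulltime_wage: float = 2340.0  # GBP/month
    parttime_wage: float = 680.0
    payroll_tax_rate: float = 0.12
    payroll_band_low: float = 702.01  # GBP/month
    payroll_band_high: float = 3863.0
    retirement_age: int = 65


@dataclass
class EmploymentInputs:
    depression_unemployed: float = 0.54
    depression_parttime: float = 0.13
    remission_unemployed: float = 0.23


@dataclass
class UnitCosts:
    """Unit costs (GBP 2019) used for scenario deltas and the direct-cost split."""

    ect_session: float = 558.0
    esketamine_per_28mg: float = 163.0
    travel_per_visit: float = 18.80
    gp_visit: float = 39.0
    psychiatrist_visit: float = 176.0
    nurse_administration: float = 44.0
    antidepressant_cycle: float = 8.0
    trd_residual_care_cycle: float = 600.0
    # informal-care calibration: GBP per cycle by health-state class,
    # fitted so the healthcare-perspective totals of all three arms match
    # the published no-discounting rows (see docs/methods.md)
    informal_care_depression_cycle: float = 565.0
    informal_care_remission_cycle: float = 0.0
    # average esketamine milligrams dispensed per 30-day cycle, by phase
    esk_mg_induction: float = 546.0
    esk_mg_maintenance_month1: float = 280.0
    esk_mg_maintenance_biweekly: float = 140.0

    @property
    def esketamine_per_mg(self) -> float:
        return self.esketamine_per_28mg / 28.0


@dataclass
class StateCostRow:
    """Societal per-cycle cost of one state/phase, by age band, plus the
    number of travel-liable clinic visits its schedule implies."""

    societal_lt65: float
    societal_ge65: float
    travel_visits: int = 0
    direct_override: float | None = None


def _default_state_costs() -> dict[str, StateCostRow]:
    # Keys are "<arm>/<state or phase>"; values are the published societal
    # totals for age <65 and >=65.  State D is arm-independent as printed.
    return {
        "ect/AC": StateCostRow(7932.0, 6321.0, travel_visits=8),
        "ect/B_standard": StateCostRow(701.0, 118.0),
        "ect/B_mect_month1": StateCostRow(3313.0, 2730.0, travel_visits=4),
        "ect/B_mect_ongoing": StateCostRow(2161.0, 1578.0, travel_visits=2),
        "esk/AC": StateCostRow(7210.0, 5599.0, travel_visits=8),
        "esk/B_month1": StateCostRow(2882.0, 2299.0, travel_visits=4),
        "esk/B_month2to5": StateCostRow(1583.0, 1000.0, travel_visits=2),
        "esk/B_month6": StateCostRow(1890.0, 1307.0, travel_visits=2),
        "any/D": StateCostRow(2729.0, 1119.0),
        "any/EF": StateCostRow(701.0, 118.0),
    }


@dataclass
class ParameterBundle:
    settings: ModelSettings = field(default_factory=ModelSettings)
    transitions: TransitionInputs = field(default_factory=TransitionInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    wages: WageInputs = field(default_factory=WageInputs)
    employment: EmploymentInputs = field(default_factory=EmploymentInputs)
    unit_costs: UnitCosts = field(default_factory=UnitCosts)
    state_costs: dict[str, StateCostRow] = field(default_factory=_default_state_costs)


def default_parameters() -> ParameterBundle:
    """The complete published parameterisation (GBP 2019)."""
    return ParameterBundle()


# ---------------------------------------------------------------------------
# validation


def _check_prob(violations: list[str], name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        violations.append(f"{name}: probability out of [0, 1] (got {value})")


def validate(bundle: ParameterBundle) -> list[str]:
    """Return a list of invariant violations; empty iff the bundle is valid."""
    v: list[str] = []
    s = bundle.settings
    if not 0.0 <= s.annual_discount_rate < 1.0:
        v.append(f"settings.annual_discount_rate: out of [0, 1) (got {s.annual_discount_rate})")
    if s.horizon_years <= 0:
        v.append("settings.horizon_years: must be positive")
    if s.start_age + s.horizon_years > 120:
        v.append("settings: start_age + horizon exceeds 120 years")
    if s.cycle_length_days <= 0:
        v.append("settings.cycle_length_days: must be positive")

    t = bundle.transitions
    for name in (
        "tpA2B_ect", "tpC2B_ect", "tpB2C_ect", "tpB2C_mect",
        "tpA2B_esk", "tpC2B_esk", "tpB2C_esk",
        "tpDepression2Death", "tpD2E", "tpE2D",
    ):
        _check_prob(v, f"transitions.{name}", getattr(t, name))
    for band, p in t.remission_mortality.items():
        _check_prob(v, f"transitions.remission_mortality[{band}]", p)
    bands = sorted(t.remission_mortality)
    probs = [t.remission_mortality[b] for b in bands]
    if any(b > a for a, b in zip(probs, probs[1:])) and probs != sorted(probs):
        v.append("transitions.remission_mortality: must be non-decreasing in age band")
    # exit probabilities of each depression state must leave residual mass
    for label, exits in (
        ("A (ECT)", t.tpA2B_ect + t.tpDepression2Death),
        ("C (ECT)", t.tpC2B_ect + t.tpDepression2Death),
        ("A (esketamine)", t.tpA2B_esk + t.tpDepression2Death),
        ("C (esketamine)", t.tpC2B_esk + t.tpDepression2Death),
        ("D", t.tpD2E + t.tpDepression2Death),
    ):
        if exits >= 1.0:
            v.append(f"transitions: exit probabilities from state {label} sum to >= 1")

    u = bundle.utilities
    if not 0.0 <= u.annual_depression <= u.annual_remission <= 1.0:
        v.append("utilities: require 0 <= depression <= remission <= 1")

    w = bundle.wages
    if w.payroll_band_low >= w.payroll_band_high:
        v.append("wages: payroll_band_low must be below payroll_band_high")
    if w.fulltime_wage < 0 or w.parttime_wage < 0:
        v.append("wages: wages must be non-negative")

    e = bundle.employment
    for name in ("depression_unemployed", "depression_parttime", "remission_unemployed"):
        _check_prob(v, f"employment.{name}", getattr(e, name))
    if e.depression_unemployed + e.depression_parttime > 1.0:
        v.append("employment: depression unemployed + part-time fractions exceed 1")

    for fld in dataclasses.fields(bundle.unit_costs):
        val = getattr(bundle.unit_costs, fld.name)
        if isinstance(val, (int, float)) and val < 0:
            v.append(f"unit_costs.{fld.name}: must be non-negative")

    for key, row in bundle.state_costs.items():
        if row.societal_lt65 < 0 or row.societal_ge65 < 0:
            v.append(f"state_costs[{key}]: costs must be non-negative")
        if row.societal_ge65 > row.societal_lt65:
            v.append(f"state_costs[{key}]: >=65 cost exceeds <65 cost")
    return v


# ---------------------------------------------------------------------------
# config I/O


_ENUM_FIELDS = {
    "arm": Arm,
    "variant": Variant,
    "perspective": Perspective,
    "discount_convention": DiscountConvention,
}

_SECTIONS = (
    ("settings", ModelSettings),
    ("transitions", TransitionInputs),
    ("utilities", UtilityInputs),
    ("wages", WageInputs),
    ("employment", EmploymentInputs),
    ("unit_costs", UnitCosts),
)


def _to_dict(bundle: ParameterBundle) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for section, _cls in _SECTIONS:
        obj = getattr(bundle, section)
        d = {}
        for fld in dataclasses.fields(obj):
            val = getattr(obj, fld.name)
            if isinstance(val, enum.Enum):
                val = val.value
            d[fld.name] = val
        out[section] = d
    out["state_costs"] = {
        key: {
            "societal_lt65": row.societal_lt65,
            "societal_ge65": row.societal_ge65,
            "travel_visits": row.travel_visits,
            **({"direct_override": row.direct_override} if row.direct_override is not None else {}),
        }
        for key, row in bundle.state_costs.items()
    }
    return out


def save_config(bundle: ParameterBundle, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(bundle), fh, sort_keys=False)


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> ParameterBundle:
    """Load a bundle from YAML; missing fields fall back to defaults,
    unknown fields raise ``ConfigError`` naming the field."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    bundle = ParameterBundle()
    known_sections = {name for name, _ in _SECTIONS} | {"state_costs"}
    for section in raw:
        if section not in known_sections:
            raise ConfigError(f"unknown config section: {section}")

    for section, cls in _SECTIONS:
        data = raw.get(section, {}) or {}
        obj = getattr(bundle, section)
        names = {f.name for f in dataclasses.fields(cls)}
        for key, val in data.items():
            if key not in names:
                raise ConfigError(f"unknown field {section}.{key}")
            if key == "remission_mortality":
                val = {int(k): float(p) for k, p in val.items()}
            elif key in _ENUM_FIELDS:
                val = _ENUM_FIELDS[key](val)
            setattr(obj, key, val)

    if "state_costs" in raw and raw["state_costs"]:
        costs: dict[str, StateCostRow] = dict(bundle.state_costs)
        for key, row in raw["state_costs"].items():
            costs[key] = StateCostRow(
                societal_lt65=float(row["societal_lt65"]),
                societal_ge65=float(row["societal_ge65"]),
                travel_visits=int(row.get("travel_visits", 0)),
                direct_override=row.get("direct_override"),
            )
        bundle.state_costs = costs
    return bundle
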