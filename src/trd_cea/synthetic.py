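"""Synthetic patient-level data and the microsimulation oracle.

The cohort model's transition probabilities were derived from published
trial summaries: an event proportion over a follow-up window, converted
to a 30-day probability under a constant hazard.  ``simulate_trial``
generates patient-level binary outcomes with exactly that structure, so
the derivation chain can be run in reverse (``recover_parameters``) and
its sampling properties checked without any external data.

``microsimulate`` pushes individual simulated patients through the same
expanded state space, transition matrices, costs, utilities and
discount factors as the cohort recursion (it consumes the engine's
``CohortModel`` arrays directly), providing an independent Monte-Carlo
oracle for the deterministic cohort totals: any disagreement beyond
Monte-Carlo error isolates the recursion itself, not the accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rates
from .engine import CohortModel, ScenarioMods, build_model
from .parameters import ModelSettings, ParameterBundle

__all__ = [
    "SyntheticTrial",
    "MicrosimResult",
    "simulate_trial",
    "recover_parameters",
    "microsimulate",
    "SOURCE_TRIALS",
]

# The evidence base being emulated: (window proportion, window days,
# hazard multiplier) per derivable transition parameter.  Windows follow
# the day conventions of the rates module (week = 7, six months = 182.5,
# year = 365 days).
SOURCE_TRIALS: dict[str, tuple[float, float, float]] = {
    "tpB2C_ect": (0.50, 182.5, 1.0),  # relapse within six months of successful ECT
    "tpB2C_mect": (0.31, 365.0, 1.0),  # relapse within one year on maintenance ECT
    "tpB2C_esk": (0.267, 17.7 * 7.0, 1.0),  # relapse in 17.7-week esketamine maintenance
    "tpD2E": (0.137, 5.6 * 7.0, 1.0),  # remission on standard treatment over 5.6 weeks
    "tpDepression2Death": (0.116, 4.5 * 365.0, 1.35),  # all-cause death over 4.5 years, TRD hazard ratio
}


@dataclass(frozen=True)
class SyntheticTrial:
    """Patient-level binary outcomes over a follow-up window."""

    parameter: str
    true_proportion: float
    window_days: float
    relative_risk: float
    seed: int
    outcomes: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.outcomes.size

    @property
    def observed_proportion(self) -> float:
        return float(self.outcomes.mean())

    def estimate_per_cycle(self, cycle_days: float = rates.DAYS_PER_CYCLE) -> float:
        """Per-cycle probability implied by the observed proportion,
        through the same conversion chain used for the real inputs."""
        return rates.mortality_with_relative_risk(
            self.observed_proportion, self.window_days, self.relative_risk, cycle_days
        )

    def proportion_ci(self, z: float = 1.96) -> tuple[float, float]:
        """Wilson score CI for the window proportion (near-nominal
        coverage even for small samples and rare events, unlike the
        Wald interval)."""
        p = self.observed_proportion
        n = self.n
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = (z / denom) * float(np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)))
        return max(0.0, centre - half), min(1.0, centre + half)


def simulate_trial(
    n: int,
    p_window: float,
    window_days: float,
    seed: int,
    parameter: str = "",
    relative_risk: float = 1.0,
) -> SyntheticTrial:
    """i.i.d. Bernoulli outcomes: did the event occur within the window?"""
    if n <= 0:
        raise ValueError("need at least one patient")
    if not 0.0 <= p_window <= 1.0:
        raise ValueError("event proportion must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    outcomes = (rng.random(n) < p_window).astype(np.uint8)
    return SyntheticTrial(
        parameter=parameter,
        true_proportion=p_window,
        window_days=window_days,
        relative_risk=relative_risk,
        seed=seed,
        outcomes=outcomes,
    )


def simulate_evidence_base(n: int, seed: int) -> list[SyntheticTrial]:
    """One synthetic trial (size ``n``) per derivable transition parameter."""
    return [
        simulate_trial(n, p, window, seed + i, parameter=name, relative_risk=rr)
        for i, (name, (p, window, rr)) in enumerate(SOURCE_TRIALS.items())
    ]


def recover_parameters(trials: list[SyntheticTrial]) -> dict[str, float]:
    """Per-cycle transition-probability estimates from synthetic trials,
    via the same proportion -> rate -> 30-day probability chain used to
    build the model inputs."""
    return {t.parameter: t.estimate_per_cycle() for t in trials}


@dataclass
class MicrosimResult:
    n: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    paths: np.ndarray | None = None  # (n, cycles+1) state indices if recorded
    state_names: list[str] | None = None


def microsimulate(
    settings: ModelSettings,
    bundle: ParameterBundle,
    n: int,
    seed: int,
    mods: ScenarioMods | None = None,
    record_paths: bool = False,
    model: CohortModel | None = None,
) -> MicrosimResult:
    """Simulate ``n`` individuals through the expanded state space with
    per-cycle categorical draws, accruing discounted cost and QALYs with
    the cohort engine's own arrays."""
    if n <= 0:
        raise ValueError("need at least one individual")
    model = model or build_model(settings, bundle, mods)
    rng = np.random.default_rng(seed)
    names = model.names
    start = names.index("A")
    dead = names.index("G")
    n_states = len(names)

    state = np.full(n, start, dtype=np.int64)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    paths = np.empty((n, model.horizon_cycles + 1), dtype=np.int16) if record_paths else None
    if paths is not None:
        paths[:, 0] = state

    cum_by_band = {band: np.cumsum(m, axis=1) for band, m in model.band_matrices.items()}
    for c in range(model.horizon_cycles):
        df = model.dfs[c]
        cost += df * model.costs_at(c)[state]
        qaly += df * model.utilities[state]
        cum = cum_by_band[int(model.band_for_cycle[c])]
        u = rng.random(n)
        new_state = state.copy()
        alive = state != dead
        for s in range(n_states):
            if s == dead:
                continue
            mask = alive & (state == s)
            if not mask.any():
                continue
            new_state[mask] = np.searchsorted(cum[s], u[mask], side="right")
        np.clip(new_state, 0, n_states - 1, out=new_state)
        state = new_state
        if paths is not None:
            paths[:, c + 1] = state

    return MicrosimResult(
        n=n,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        paths=paths,
        state_names=names,
    )
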