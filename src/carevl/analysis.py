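"""Comparative analyses: base case, sensitivity sweeps, thresholds,
maximal scenarios, and population scaling.

One-way sensitivity rows follow the published table semantics: a row whose
quantity exists for both screening strategies (acceptance, sensitivity,
specificity) sweeps a common value applied to both strategies' parameters
in lockstep, so the comparison varies the care environment rather than
handicapping a single strategy.  The referral-follow-up row sweeps the AI
parameter alone, because under the default model variant the ECP screen
already happens in eye care and has no separate referral stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .cohort import (
    DEFAULT_VARIANT,
    ModelVariant,
    any_vision_loss_per_100k,
    round_half_up,
    run_strategy,
)
from .params import ParameterError, ParameterSet, registry_by_name

__all__ = [
    "OutcomeSummary",
    "SensitivityResult",
    "TwoWayResult",
    "ScenarioResult",
    "Table2Row",
    "TABLE2_ROWS",
    "outcome",
    "compare_strategies",
    "one_way_sa",
    "find_threshold",
    "find_crossing",
    "two_way_sa",
    "maximal_scenario",
    "scale_to_population",
]

_STRATEGIES = ("no_screening", "ecp", "ai")


def outcome(strategy_id: str, params: ParameterSet,
            variant: ModelVariant = DEFAULT_VARIANT, horizon: int = 5) -> float:
    """Any-vision-loss per 100,000 at the horizon for one strategy."""
    trace = run_strategy(strategy_id, params, variant, horizon)
    return any_vision_loss_per_100k(trace, horizon)


@dataclass(frozen=True)
class OutcomeSummary:
    """Per-strategy outcomes with pairwise risk differences.

    ``effectiveness_ratio`` is (no_screening - ai) / (no_screening - ecp):
    how many times more vision loss screening with AI prevents than
    screening with an ECP, relative to not screening at all.
    """

    outcomes: dict[str, float]
    risk_differences: dict[str, float]
    effectiveness_ratio: float
    provenance: str
    horizon: int = 5

    def rounded(self) -> dict[str, int]:
        return {k: round_half_up(v) for k, v in self.outcomes.items()}


def compare_strategies(params: ParameterSet,
                       variant: ModelVariant = DEFAULT_VARIANT,
                       horizon: int = 5) -> OutcomeSummary:
    """Run all three strategies from the same initial cohort and parameters."""
    out = {s: outcome(s, params, variant, horizon) for s in _STRATEGIES}
    diffs = {
        "no_screening_minus_ai": out["no_screening"] - out["ai"],
        "no_screening_minus_ecp": out["no_screening"] - out["ecp"],
        "ecp_minus_ai": out["ecp"] - out["ai"],
    }
    denom = diffs["no_screening_minus_ecp"]
    ratio = diffs["no_screening_minus_ai"] / denom if denom != 0 else float("nan")
    return OutcomeSummary(out, diffs, ratio, params.provenance, horizon)


@dataclass(frozen=True)
class Table2Row:
    """One published one-way sensitivity row: the swept model quantity,
    the registry parameters it binds (lockstep), and the sweep range."""

    label: str
    metric_type: str
    param_names: tuple[str, ...]
    low: float
    high: float


TABLE2_ROWS: tuple[Table2Row, ...] = (
    Table2Row("Prevalence of metabolic DRD", "population",
              ("prevalence_metabolic",), 0.0, 0.40),
    Table2Row("Offered and accepts screening for DRD", "process_of_care",
              ("accept_screening_ecp", "accept_screening_ai"), 0.0, 1.0),
    Table2Row("Sensitivity of the DRD screening strategy", "diagnostic_accuracy",
              ("sensitivity_ecp", "sensitivity_ai"), 0.0, 1.0),
    Table2Row("Specificity of DRD screening strategy", "diagnostic_accuracy",
              ("specificity_ecp", "specificity_ai"), 0.0, 1.0),
    Table2Row("Accepts referral for eye care after a positive screen",
              "process_of_care", ("accept_referral_ai",), 0.0, 0.95),
    Table2Row("Probability of adhering with treatment", "process_of_care",
              ("adherence_metabolic",), 0.0, 1.0),
    Table2Row("Effectiveness of ophthalmic treatments", "process_of_care",
              ("ophthalmic_to_vl_treated",), 0.0, 0.50),
    Table2Row("Effectiveness of metabolic treatments", "process_of_care",
              ("metabolic_to_ophthalmic_treated",), 0.0, 0.05),
)


@dataclass(frozen=True)
class SensitivityResult:
    """One-way sweep: outcomes per strategy on a grid, preferred strategy
    per point, and any thresholds where the AI-vs-ECP preference flips."""

    param_names: tuple[str, ...]
    grid: np.ndarray
    outcomes: dict[str, np.ndarray]
    preferred: tuple[str, ...]
    thresholds: tuple[float, ...]
    ties: tuple[bool, ...]

    @property
    def dominant(self) -> str | None:
        """Strategy preferred at every grid point, else None."""
        unique = set(self.preferred)
        return unique.pop() if len(unique) == 1 else None

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({"value": self.grid})
        for s, v in self.outcomes.items():
            df[s] = v
        df["preferred"] = list(self.preferred)
        df["tie"] = list(self.ties)
        return df


def _coerce_names(param_names: str | Sequence[str]) -> tuple[str, ...]:
    names = (param_names,) if isinstance(param_names, str) else tuple(param_names)
    registry = registry_by_name()
    for n in names:
        if n not in registry:
            raise ParameterError(f"unknown parameter {n!r}")
    return names


def _default_range(names: tuple[str, ...]) -> tuple[float, float]:
    registry = registry_by_name()
    lows = [registry[n].low for n in names]
    highs = [registry[n].high for n in names]
    return min(lows), max(highs)


def _prefer(out: Mapping[str, float]) -> tuple[str, bool]:
    """Lowest vision loss wins; exact AI/ECP ties resolve to AI, flagged."""
    best = min(out.values())
    winners = [s for s in _STRATEGIES if out[s] == best]
    if "ai" in winners:
        return "ai", len(winners) > 1
    return winners[0], len(winners) > 1


def one_way_sa(param_names: str | Sequence[str], n_points: int = 101,
               params: ParameterSet | None = None,
               variant: ModelVariant = DEFAULT_VARIANT,
               value_range: tuple[float, float] | None = None,
               horizon: int = 5) -> SensitivityResult:
    """Sweep one model quantity (one parameter, or several in lockstep)
    across its range, holding everything else at ``params``."""
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    names = _coerce_names(param_names)
    if params is None:
        from .params import base_case

        params = base_case()
    lo, hi = value_range if value_range is not None else _default_range(names)
    grid = np.linspace(lo, hi, n_points)
    outcomes = {s: np.empty(n_points) for s in _STRATEGIES}
    preferred: list[str] = []
    ties: list[bool] = []
    for i, v in enumerate(grid):
        p = params.with_overrides({n: float(v) for n in names},
                                  label=f"sweep:{'+'.join(names)}")
        point = {s: outcome(s, p, variant, horizon) for s in _STRATEGIES}
        for s in _STRATEGIES:
            outcomes[s][i] = point[s]
        who, tie = _prefer(point)
        preferred.append(who)
        ties.append(tie)
    thresholds = tuple(
        t for t in (find_threshold(names, (lo, hi), params,
                                   variant=variant, horizon=horizon) or ())
    )
    return SensitivityResult(names, grid, outcomes, tuple(preferred),
                             thresholds, tuple(ties))


def find_crossing(f: Callable[[float], float], lo: float, hi: float,
                  step: float = 0.01, tol: float = 1e-6) -> tuple[float, ...]:
    """Sign changes of ``f`` on [lo, hi]: coarse grid scan refined by
    bisection (brentq) to ``tol``.  Exact zeros (ties) are not crossings;
    a root is reported only where the sign genuinely flips."""
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    n = max(2, int(round((hi - lo) / step)) + 1)
    grid = np.linspace(lo, hi, n)
    vals = np.array([f(x) for x in grid])
    signs = np.sign(vals)
    nonzero = np.flatnonzero(signs != 0)
    roots: list[float] = []
    for a, b in zip(nonzero[:-1], nonzero[1:]):
        if signs[a] * signs[b] < 0:
            roots.append(float(brentq(f, grid[a], grid[b], xtol=tol)))
    return tuple(roots)


def find_threshold(param_names: str | Sequence[str],
                   value_range: tuple[float, float] | None = None,
                   params: ParameterSet | None = None, tol: float = 1e-6,
                   variant: ModelVariant = DEFAULT_VARIANT,
                   horizon: int = 5) -> tuple[float, ...]:
    """Values of the swept quantity where the AI and ECP outcomes cross
    (empty when one strategy is preferred throughout)."""
    names = _coerce_names(param_names)
    if params is None:
        from .params import base_case

        params = base_case()
    lo, hi = value_range if value_range is not None else _default_range(names)

    def diff(v: float) -> float:
        p = params.with_overrides({n: float(v) for n in names},
                                  label="threshold")
        return outcome("ai", p, variant, horizon) - outcome("ecp", p, variant, horizon)

    return find_crossing(diff, lo, hi, step=0.01, tol=tol)


@dataclass(frozen=True)
class TwoWayResult:
    """Preferred-strategy surface over the product of two parameter grids."""

    param_a: str
    param_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    preferred: np.ndarray  # (len(grid_a), len(grid_b)) of strategy labels

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.preferred, index=self.grid_a,
                            columns=self.grid_b).rename_axis(
            index=self.param_a, columns=self.param_b)


def two_way_sa(param_a: str, param_b: str,
               grids: tuple[int, int] | tuple[np.ndarray, np.ndarray] = (21, 21),
               params: ParameterSet | None = None,
               variant: ModelVariant = DEFAULT_VARIANT,
               horizon: int = 5) -> TwoWayResult:
    """Preferred strategy over the full rectangle of two parameter ranges."""
    if param_a == param_b:
        raise ParameterError("two-way analysis needs two distinct parameters")
    (name_a,), (name_b,) = _coerce_names(param_a), _coerce_names(param_b)
    if params is None:
        from .params import base_case

        params = base_case()
    registry = registry_by_name()

    def as_grid(g, name):
        if isinstance(g, (int, np.integer)):
            spec = registry[name]
            return np.linspace(spec.low, spec.high, int(g))
        return np.asarray(g, dtype=float)

    grid_a = as_grid(grids[0], name_a)
    grid_b = as_grid(grids[1], name_b)
    preferred = np.empty((grid_a.size, grid_b.size), dtype=object)
    for i, va in enumerate(grid_a):
        for j, vb in enumerate(grid_b):
            p = params.with_overrides({name_a: float(va), name_b: float(vb)},
                                      label="two_way")
            point = {s: outcome(s, p, variant, horizon) for s in _STRATEGIES}
            preferred[i, j], _ = _prefer(point)
    return TwoWayResult(name_a, name_b, grid_a, grid_b, preferred)


@dataclass(frozen=True)
class ScenarioResult:
    """Outcomes under overridden parameters, with deltas vs the base run."""

    overrides: dict[str, float]
    summary: OutcomeSummary
    base_summary: OutcomeSummary
    deltas: dict[str, float] = field(default_factory=dict)  # base - scenario


def maximal_scenario(overrides: Mapping[str, float], params: ParameterSet,
                     variant: ModelVariant = DEFAULT_VARIANT,
                     horizon: int = 5,
                     label: str = "maximal") -> ScenarioResult:
    """Re-run with process-of-care parameters overridden (e.g. adherence at
    100%) and report each strategy's reduction vs its own base case."""
    base = compare_strategies(params, variant, horizon)
    scenario = compare_strategies(
        params.with_overrides(dict(overrides), label=label), variant, horizon)
    deltas = {s: base.outcomes[s] - scenario.outcomes[s] for s in _STRATEGIES}
    return ScenarioResult(dict(overrides), scenario, base, deltas)


def scale_to_population(risk_diff_per_100k: float, population: float) -> int:
    """People affected when a per-100,000 risk difference is applied to a
    population (e.g. 90 per 100,000 x 30 million -> 27,000)."""
    if population < 0:
        raise ParameterError("population must be >= 0")
    return round_half_up(risk_diff_per_100k * population / 1e5)
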