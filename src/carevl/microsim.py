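"""Individual-level Monte-Carlo oracle and random-parameter generator.

The microsimulation replays the same care rules as the cohort model, but
as per-person Bernoulli draws: each simulated patient accepts or refuses
screening, tests positive or negative, follows up, adheres, and
progresses, cycle by cycle.  It shares no code path with the transition
matrix, so agreement between the two (within binomial noise) validates
the cohort implementation.

Draws are organised as a fixed block of uniforms per person per cycle,
one column per decision role, so that two runs with the same seed but
different parameter values reuse common random numbers — useful for
variance-reduced monotonicity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import StrategyConfig
from .cohort import (
    DEFAULT_VARIANT,
    HealthState,
    ModelVariant,
    N_STATES,
    effective_detection,
    initial_distribution,
)
from .params import ParameterError, ParameterSet, ParameterSpec, registry_by_name

__all__ = ["MicrosimResult", "simulate_individuals", "sample_parameter_sets"]

_S = HealthState
_VL = (int(_S.VL_UNTX), int(_S.VL_TX), int(_S.IRREV_VL))

# uniform-draw roles, one column each per person-cycle
_U_ACCEPT, _U_POSITIVE, _U_FOLLOWUP, _U_ADHERE, _U_PROGRESS, _U_LAND = range(6)


@dataclass(frozen=True)
class MicrosimResult:
    """End-of-horizon state counts for a simulated cohort."""

    n_individuals: int
    seed: int
    strategy: str
    counts: dict[str, int]
    proportion_vision_loss: float
    standard_error: float
    trajectories: np.ndarray | None = None

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.n_individuals


def _landing_treated(mode: str, successor_adherence: float,
                     u: np.ndarray) -> np.ndarray:
    """Boolean: progression out of a treated state lands treated."""
    if mode == "adherence":
        return u < successor_adherence
    if mode == "stay":
        return np.ones_like(u, dtype=bool)
    return np.zeros_like(u, dtype=bool)


def simulate_individuals(cfg: StrategyConfig, params: ParameterSet, n: int,
                         seed: int, variant: ModelVariant = DEFAULT_VARIANT,
                         horizon: int = 5,
                         record_trajectories: bool = False) -> MicrosimResult:
    """Simulate ``n`` patients for ``horizon`` annual cycles."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)

    d = effective_detection(cfg, variant)
    # stage-level cascade probabilities (their product equals d)
    if cfg.strategy_id == "ecp" and variant.ecp_screen_is_eye_care:
        p_accept, p_follow = cfg.p_accept_screening, 1.0
    else:
        p_accept, p_follow = cfg.p_accept_screening, cfg.p_accept_referral
    sens = cfg.sensitivity

    a_met = params["adherence_metabolic"]
    a_oph = params["adherence_ophthalmic"]
    a_vl = params["adherence_vl"]
    c_vl = params["vl_accept_referral"] * a_vl
    q_nm = params["no_drd_to_metabolic"]
    q_mo = params["metabolic_to_ophthalmic"]
    q_ov = params["ophthalmic_to_vl"]
    q_vi = params["vl_to_irreversible"]
    r_mo = params["metabolic_to_ophthalmic_treated"]
    r_ov = params["ophthalmic_to_vl_treated"]
    r_vi = params["vl_to_irreversible_treated"]
    land = variant.treated_landing
    percycle = variant.adherence_persistence == "percycle"

    init = initial_distribution(params, variant=variant)
    state = np.searchsorted(np.cumsum(init), rng.random(n)).astype(np.int8)
    state = np.minimum(state, N_STATES - 1)

    if variant.enrollment_screen != "none":
        u = rng.random((n, 3))
        detected = (u[:, 0] < p_accept) & (u[:, 1] < sens) & (u[:, 2] < p_follow)
        if variant.enrollment_screen == "adherence":
            u_adh = rng.random(n)
            enter_met = detected & (u_adh < a_met)
            enter_oph = detected & (u_adh < a_oph)
        else:
            enter_met = enter_oph = detected
        state[(state == _S.MET_UNTX) & enter_met] = _S.MET_TX
        state[(state == _S.OPH_UNTX) & enter_oph] = _S.OPH_TX

    traj = None
    if record_trajectories:
        traj = np.empty((n, horizon + 1), dtype=np.int8)
        traj[:, 0] = state

    for t in range(horizon):
        u = rng.random((n, 6))
        new = state.copy()
        detected = (u[:, _U_ACCEPT] < p_accept) & (u[:, _U_POSITIVE] < sens) \
            & (u[:, _U_FOLLOWUP] < p_follow)

        # untreated metabolic
        mask = state == _S.MET_UNTX
        enter = mask & detected & (u[:, _U_ADHERE] < a_met)
        prog_tx = enter & (u[:, _U_PROGRESS] < r_mo)
        new[enter & ~prog_tx] = _S.MET_TX
        tx_land = _landing_treated(land, a_oph, u[:, _U_LAND])
        new[prog_tx & tx_land] = _S.OPH_TX
        new[prog_tx & ~tx_land] = _S.OPH_UNTX
        stay = mask & ~enter
        new[stay & (u[:, _U_PROGRESS] < q_mo)] = _S.OPH_UNTX

        # untreated ophthalmic
        mask = state == _S.OPH_UNTX
        enter = mask & detected & (u[:, _U_ADHERE] < a_oph)
        prog_tx = enter & (u[:, _U_PROGRESS] < r_ov)
        new[enter & ~prog_tx] = _S.OPH_TX
        tx_land = _landing_treated(land, a_vl, u[:, _U_LAND])
        new[prog_tx & tx_land] = _S.VL_TX
        new[prog_tx & ~tx_land] = _S.VL_UNTX
        stay = mask & ~enter
        prog_u = stay & (u[:, _U_PROGRESS] < q_ov)
        in_care = u[:, _U_LAND] < c_vl
        new[prog_u & in_care] = _S.VL_TX
        new[prog_u & ~in_care] = _S.VL_UNTX

        # treated metabolic
        mask = state == _S.MET_TX
        adherent = mask & ((u[:, _U_ADHERE] < a_met) if percycle else True)
        prog = adherent & (u[:, _U_PROGRESS] < r_mo)
        tx_land = _landing_treated(land, a_oph, u[:, _U_LAND])
        new[prog & tx_land] = _S.OPH_TX
        new[prog & ~tx_land] = _S.OPH_UNTX
        lapsed = mask & ~adherent
        new[lapsed & (u[:, _U_PROGRESS] < q_mo)] = _S.OPH_UNTX
        new[lapsed & ~(u[:, _U_PROGRESS] < q_mo)] = _S.MET_UNTX

        # treated ophthalmic
        mask = state == _S.OPH_TX
        adherent = mask & ((u[:, _U_ADHERE] < a_oph) if percycle else True)
        prog = adherent & (u[:, _U_PROGRESS] < r_ov)
        tx_land = _landing_treated(land, a_vl, u[:, _U_LAND])
        new[prog & tx_land] = _S.VL_TX
        new[prog & ~tx_land] = _S.VL_UNTX
        lapsed = mask & ~adherent
        prog_u = lapsed & (u[:, _U_PROGRESS] < q_ov)
        in_care = u[:, _U_LAND] < c_vl
        new[prog_u & in_care] = _S.VL_TX
        new[prog_u & ~in_care] = _S.VL_UNTX
        new[lapsed & ~prog_u] = _S.OPH_UNTX

        # symptomatic vision loss
        mask = state == _S.VL_UNTX
        in_care = mask & (u[:, _U_ADHERE] < c_vl)
        new[in_care & (u[:, _U_PROGRESS] < r_vi)] = _S.IRREV_VL
        new[in_care & ~(u[:, _U_PROGRESS] < r_vi)] = _S.VL_TX
        no_care = mask & ~in_care
        new[no_care & (u[:, _U_PROGRESS] < q_vi)] = _S.IRREV_VL

        mask = state == _S.VL_TX
        new[mask & (u[:, _U_PROGRESS] < r_vi)] = _S.IRREV_VL

        mask = state == _S.NO_DRD
        new[mask & (u[:, _U_PROGRESS] < q_nm)] = _S.MET_UNTX

        state = new
        if traj is not None:
            traj[:, t + 1] = state

    counts_arr = np.bincount(state, minlength=N_STATES)
    counts = {s.name: int(counts_arr[s]) for s in HealthState}
    p_vl = float(counts_arr[list(_VL)].sum() / n)
    se = float(np.sqrt(max(p_vl * (1.0 - p_vl), 1.0 / n) / n))
    return MicrosimResult(n, seed, cfg.strategy_id, counts, p_vl, se, traj)


def sample_parameter_sets(registry: tuple[ParameterSpec, ...] | None,
                          n_sets: int, seed: int) -> list[ParameterSet]:
    """Parameter sets drawn uniformly within each spec's (low, high) range,
    for invariant stress testing."""
    if n_sets < 1:
        raise ParameterError("n_sets must be >= 1")
    specs = registry_by_name(registry)
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        values = {name: float(rng.uniform(s.low, s.high))
                  for name, s in specs.items()}
        sets.append(ParameterSet(values, provenance=f"sampled:{seed}"))
    return sets
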