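"""Annual-cycle Markov cohort model of diabetic retinal disease.

Eight health states track disease stage (none, metabolic, ophthalmic,
vision loss, irreversible vision loss) and, within each disease stage,
whether the person is on the recommended treatment.  A closed cohort is
evolved for five one-year cycles under one of three screening strategies;
the outcome is the occupancy of the vision-loss states at the horizon,
which equals cumulative incidence because vision loss never reverts.

Because the published model's full decision tree is not available, the
structural choices that the published tables leave open are collected in
:class:`ModelVariant`; the default variant is the one the structural
harness (:mod:`carevl.variants`) identifies as reproducing the published
base case.  See ``docs/methods.md`` for the reconstruction rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .cascade import StrategyConfig, detection_probability, strategy_from_parameters
from .params import ParameterError, ParameterSet

__all__ = [
    "HealthState",
    "ModelVariant",
    "DEFAULT_VARIANT",
    "TransitionMatrix",
    "CohortTrace",
    "ModelStructureError",
    "effective_detection",
    "initial_distribution",
    "apply_enrollment_screen",
    "build_transition_matrix",
    "run_cohort",
    "run_strategy",
    "any_vision_loss_per_100k",
    "round_half_up",
]


class HealthState(IntEnum):
    NO_DRD = 0
    MET_UNTX = 1
    MET_TX = 2
    OPH_UNTX = 3
    OPH_TX = 4
    VL_UNTX = 5
    VL_TX = 6
    IRREV_VL = 7


_VL_STATES = (HealthState.VL_UNTX, HealthState.VL_TX, HealthState.IRREV_VL)
N_STATES = len(HealthState)

_ENROLLMENT_MODES = ("none", "adherence", "detection")
_PERSISTENCE_MODES = ("percycle", "permanent")
_LANDING_MODES = ("adherence", "stay", "untreated")


class ModelStructureError(ValueError):
    """Raised when a transition matrix cannot be constructed."""


@dataclass(frozen=True)
class ModelVariant:
    """Structural choices left open by the published model description.

    enrollment_screen
        Whether the prevalent cohort is screened once at enrollment
        (the decision-tree node ahead of the Markov model) and whether
        that entry into care is gated by treatment adherence
        ("adherence"), by detection alone ("detection"), or absent.
    adherence_persistence
        "percycle": each cycle a person in a treated state adheres with
        the stage's adherence probability (treated progression, remains
        treated) or lapses (natural-history progression, reverts to the
        untreated state).  "permanent": treated status persists.
    treated_landing
        Where progression out of a treated state lands in the successor
        stage: treated substate with the successor stage's adherence
        ("adherence"), always treated ("stay"), or always untreated.
    ecp_screen_is_eye_care
        If True, a positive screen by an eye care provider needs no
        separate referral step (the exam already happens in eye care), so
        the ECP cascade is acceptance x sensitivity.
    count_vl_prevalence
        If True, the published prevalence of DRD with vision loss is
        seeded into VL_UNTX and counted in the outcome.
    """

    enrollment_screen: str = "detection"
    adherence_persistence: str = "percycle"
    treated_landing: str = "untreated"
    ecp_screen_is_eye_care: bool = True
    count_vl_prevalence: bool = True

    def __post_init__(self) -> None:
        if self.enrollment_screen not in _ENROLLMENT_MODES:
            raise ValueError(f"enrollment_screen {self.enrollment_screen!r}")
        if self.adherence_persistence not in _PERSISTENCE_MODES:
            raise ValueError(f"adherence_persistence {self.adherence_persistence!r}")
        if self.treated_landing not in _LANDING_MODES:
            raise ValueError(f"treated_landing {self.treated_landing!r}")

    @property
    def label(self) -> str:
        return (f"enroll={self.enrollment_screen},"
                f"adherence={self.adherence_persistence},"
                f"landing={self.treated_landing},"
                f"ecp_eye_care={self.ecp_screen_is_eye_care},"
                f"count_vl={self.count_vl_prevalence}")


DEFAULT_VARIANT = ModelVariant()


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic annual transition matrix for one strategy."""

    matrix: np.ndarray
    strategy: str
    cycle_length: float = 1.0

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (N_STATES, N_STATES):
            raise ModelStructureError(f"expected {N_STATES}x{N_STATES}, got {m.shape}")
        bad = np.argwhere((m < 0) | (m > 1))
        if bad.size:
            i, j = bad[0]
            raise ModelStructureError(
                f"entry [{HealthState(i).name} -> {HealthState(j).name}] = "
                f"{m[i, j]} outside [0, 1]"
            )
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ModelStructureError(f"row sums {m.sum(axis=1)} != 1")


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle: (n_cycles + 1) x 8, rows sum to one."""

    occupancy: np.ndarray
    strategy: str
    provenance: str = ""

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def vision_loss(self, cycle: int) -> float:
        """Combined occupancy of the vision-loss states at ``cycle``."""
        return float(self.occupancy[cycle, list(_VL_STATES)].sum())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.occupancy,
                            columns=[s.name for s in HealthState]).rename_axis("cycle")


def effective_detection(cfg: StrategyConfig, variant: ModelVariant) -> float:
    """Per-cycle detection probability as used by the transition model.

    For the ECP strategy under the default variant the screen already takes
    place in eye care, so the separate referral-follow-up stage drops out.
    """
    if cfg.strategy_id == "ecp" and variant.ecp_screen_is_eye_care:
        return cfg.p_accept_screening * cfg.sensitivity
    return detection_probability(cfg, disease_present=True)


def initial_distribution(params: ParameterSet,
                         include_vl_prevalence: bool | None = None,
                         variant: ModelVariant = DEFAULT_VARIANT) -> np.ndarray:
    """Enrollment state occupancy from the prevalence parameters.

    Prevalent metabolic and ophthalmic disease start untreated; when
    ``include_vl_prevalence`` (default: the variant's setting) prevalent
    vision loss is seeded into VL_UNTX, otherwise it is excluded and the
    remainder goes to NO_DRD.
    """
    if include_vl_prevalence is None:
        include_vl_prevalence = variant.count_vl_prevalence
    p_met = params["prevalence_metabolic"]
    p_oph = params["prevalence_ophthalmic"]
    p_vl = params["prevalence_vision_loss"] if include_vl_prevalence else 0.0
    total = p_met + p_oph + p_vl
    if total > 1.0:
        raise ParameterError(f"prevalences sum to {total} > 1")
    init = np.zeros(N_STATES)
    init[HealthState.MET_UNTX] = p_met
    init[HealthState.OPH_UNTX] = p_oph
    init[HealthState.VL_UNTX] = p_vl
    init[HealthState.NO_DRD] = 1.0 - total
    return init


def apply_enrollment_screen(init: np.ndarray, cfg: StrategyConfig,
                            params: ParameterSet,
                            variant: ModelVariant = DEFAULT_VARIANT) -> np.ndarray:
    """One screening pass over the prevalent untreated cohort at enrollment."""
    out = init.astype(float).copy()
    if variant.enrollment_screen == "none":
        return out
    d = effective_detection(cfg, variant)
    if variant.enrollment_screen == "adherence":
        e_met = d * params["adherence_metabolic"]
        e_oph = d * params["adherence_ophthalmic"]
    else:  # detection-gated: diagnosis starts care, adherence acts per cycle
        e_met = e_oph = d
    for untx, tx, e in ((HealthState.MET_UNTX, HealthState.MET_TX, e_met),
                        (HealthState.OPH_UNTX, HealthState.OPH_TX, e_oph)):
        out[tx] += out[untx] * e
        out[untx] *= 1.0 - e
    return out


def _landing_split(mode: str, successor_adherence: float) -> tuple[float, float]:
    """(treated, untreated) landing fractions for progression out of a
    treated state."""
    if mode == "adherence":
        return successor_adherence, 1.0 - successor_adherence
    if mode == "stay":
        return 1.0, 0.0
    return 0.0, 1.0


def build_transition_matrix(cfg: StrategyConfig, params: ParameterSet,
                            variant: ModelVariant = DEFAULT_VARIANT) -> TransitionMatrix:
    """Annual transition matrix for one strategy.

    Screening acts first within a cycle: an untreated person who clears the
    cascade progresses on the treated row that same cycle; everyone then
    takes one annual progression draw.
    """
    S = HealthState
    d = effective_detection(cfg, variant)
    a_met = params["adherence_metabolic"]
    a_oph = params["adherence_ophthalmic"]
    a_vl = params["adherence_vl"]
    e_met = d * a_met
    e_oph = d * a_oph
    c_vl = params["vl_accept_referral"] * a_vl

    q_nm = params["no_drd_to_metabolic"]
    q_mo = params["metabolic_to_ophthalmic"]
    q_ov = params["ophthalmic_to_vl"]
    q_vi = params["vl_to_irreversible"]
    r_mo = params["metabolic_to_ophthalmic_treated"]
    r_ov = params["ophthalmic_to_vl_treated"]
    r_vi = params["vl_to_irreversible_treated"]

    land_oph = _landing_split(variant.treated_landing, a_oph)
    land_vl = _landing_split(variant.treated_landing, a_vl)

    m = np.zeros((N_STATES, N_STATES))
    m[S.NO_DRD, S.NO_DRD] = 1.0 - q_nm
    m[S.NO_DRD, S.MET_UNTX] = q_nm

    # untreated metabolic: cascade, then progression on the matching row
    m[S.MET_UNTX, S.MET_TX] = e_met * (1.0 - r_mo)
    m[S.MET_UNTX, S.OPH_TX] = e_met * r_mo * land_oph[0]
    m[S.MET_UNTX, S.OPH_UNTX] = e_met * r_mo * land_oph[1]
    m[S.MET_UNTX, S.MET_UNTX] = (1.0 - e_met) * (1.0 - q_mo)
    m[S.MET_UNTX, S.OPH_UNTX] += (1.0 - e_met) * q_mo

    # untreated ophthalmic; vision-loss entry splits by the symptomatic
    # care probability (vision loss bypasses screening)
    m[S.OPH_UNTX, S.OPH_TX] = e_oph * (1.0 - r_ov)
    m[S.OPH_UNTX, S.VL_TX] = e_oph * r_ov * land_vl[0]
    m[S.OPH_UNTX, S.VL_UNTX] = e_oph * r_ov * land_vl[1]
    m[S.OPH_UNTX, S.OPH_UNTX] = (1.0 - e_oph) * (1.0 - q_ov)
    m[S.OPH_UNTX, S.VL_TX] += (1.0 - e_oph) * q_ov * c_vl
    m[S.OPH_UNTX, S.VL_UNTX] += (1.0 - e_oph) * q_ov * (1.0 - c_vl)

    # treated stages
    if variant.adherence_persistence == "percycle":
        m[S.MET_TX, S.MET_TX] = a_met * (1.0 - r_mo)
        m[S.MET_TX, S.OPH_TX] = a_met * r_mo * land_oph[0]
        m[S.MET_TX, S.OPH_UNTX] = a_met * r_mo * land_oph[1]
        m[S.MET_TX, S.MET_UNTX] = (1.0 - a_met) * (1.0 - q_mo)
        m[S.MET_TX, S.OPH_UNTX] += (1.0 - a_met) * q_mo

        m[S.OPH_TX, S.OPH_TX] = a_oph * (1.0 - r_ov)
        m[S.OPH_TX, S.VL_TX] = a_oph * r_ov * land_vl[0]
        m[S.OPH_TX, S.VL_UNTX] = a_oph * r_ov * land_vl[1]
        m[S.OPH_TX, S.OPH_UNTX] = (1.0 - a_oph) * (1.0 - q_ov)
        m[S.OPH_TX, S.VL_TX] += (1.0 - a_oph) * q_ov * c_vl
        m[S.OPH_TX, S.VL_UNTX] += (1.0 - a_oph) * q_ov * (1.0 - c_vl)
    else:  # permanent treated status
        m[S.MET_TX, S.MET_TX] = 1.0 - r_mo
        m[S.MET_TX, S.OPH_TX] = r_mo * land_oph[0]
        m[S.MET_TX, S.OPH_UNTX] = r_mo * land_oph[1]
        m[S.OPH_TX, S.OPH_TX] = 1.0 - r_ov
        m[S.OPH_TX, S.VL_TX] = r_ov * land_vl[0]
        m[S.OPH_TX, S.VL_UNTX] = r_ov * land_vl[1]

    # symptomatic vision loss: direct care pathway each cycle
    m[S.VL_UNTX, S.VL_TX] = c_vl * (1.0 - r_vi)
    m[S.VL_UNTX, S.IRREV_VL] = c_vl * r_vi + (1.0 - c_vl) * q_vi
    m[S.VL_UNTX, S.VL_UNTX] = (1.0 - c_vl) * (1.0 - q_vi)

    m[S.VL_TX, S.VL_TX] = 1.0 - r_vi
    m[S.VL_TX, S.IRREV_VL] = r_vi
    m[S.IRREV_VL, S.IRREV_VL] = 1.0

    return TransitionMatrix(m, strategy=cfg.strategy_id)


def run_cohort(init: np.ndarray, matrix: TransitionMatrix,
               n_cycles: int, provenance: str = "") -> CohortTrace:
    """Evolve a closed cohort: row ``t+1 = row t @ matrix``.  No half-cycle
    correction is applied."""
    init = np.asarray(init, dtype=float)
    if init.shape != (N_STATES,):
        raise ModelStructureError(f"initial vector shape {init.shape}")
    if n_cycles < 0:
        raise ModelStructureError("n_cycles must be >= 0")
    occ = np.empty((n_cycles + 1, N_STATES))
    occ[0] = init
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ matrix.matrix
    return CohortTrace(occ, strategy=matrix.strategy, provenance=provenance)


def run_strategy(strategy_id: str, params: ParameterSet,
                 variant: ModelVariant = DEFAULT_VARIANT,
                 horizon: int = 5) -> CohortTrace:
    """Convenience: configure, enroll, and evolve one strategy."""
    cfg = strategy_from_parameters(strategy_id, params)
    init = initial_distribution(params, variant=variant)
    init = apply_enrollment_screen(init, cfg, params, variant)
    matrix = build_transition_matrix(cfg, params, variant)
    return run_cohort(init, matrix, horizon, provenance=params.provenance)


def any_vision_loss_per_100k(trace: CohortTrace, horizon_years: int) -> float:
    """Any-vision-loss occupancy at the horizon, per 100,000 (unrounded;
    equals cumulative incidence because vision loss never reverts)."""
    if horizon_years > trace.n_cycles:
        raise ModelStructureError(
            f"horizon {horizon_years} beyond trace ({trace.n_cycles} cycles)")
    return 1e5 * trace.vision_loss(horizon_years)


def round_half_up(x: float) -> int:
    """Report per-100,000 figures as integers, halves away from zero."""
    return int(math.floor(x + 0.5))
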