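"""Screening cascade: strategy definitions and per-cycle care probabilities.

A screening strategy turns disease presence into treatment entry through a
chain of independent chance stages: the patient accepts the exam, the exam
detects disease (sensitivity; or falsely flags a healthy eye, 1 -
specificity), the patient follows up on a positive result, and finally
adheres to the recommended treatment.  Each stage is a Bernoulli event and
the per-cycle probabilities below are their products.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterError, ParameterSet

__all__ = [
    "STRATEGIES",
    "StrategyConfig",
    "strategy_from_parameters",
    "detection_probability",
    "treatment_entry_probability",
    "vision_loss_care_probability",
]

STRATEGIES = ("no_screening", "ecp", "ai")

_ADHERENCE_BY_STAGE = {
    "metabolic": "adherence_metabolic",
    "ophthalmic": "adherence_ophthalmic",
}


@dataclass(frozen=True)
class StrategyConfig:
    """Screening-cascade probabilities for one strategy."""

    strategy_id: str
    p_accept_screening: float
    sensitivity: float
    specificity: float
    p_accept_referral: float

    def __post_init__(self) -> None:
        if self.strategy_id not in STRATEGIES:
            raise ParameterError(f"unknown strategy {self.strategy_id!r}")
        for name in ("p_accept_screening", "sensitivity", "specificity",
                     "p_accept_referral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}: {v} outside [0, 1]")
        if self.strategy_id == "no_screening" and self.p_accept_screening != 0.0:
            raise ParameterError("no_screening requires p_accept_screening = 0")


def strategy_from_parameters(strategy_id: str,
                             params: ParameterSet) -> StrategyConfig:
    """Build the cascade configuration of a strategy from a ParameterSet."""
    if strategy_id == "no_screening":
        return StrategyConfig(strategy_id, 0.0, 0.0, 1.0, 0.0)
    if strategy_id not in STRATEGIES:
        raise ParameterError(f"unknown strategy {strategy_id!r}")
    suffix = strategy_id
    return StrategyConfig(
        strategy_id,
        p_accept_screening=params[f"accept_screening_{suffix}"],
        sensitivity=params[f"sensitivity_{suffix}"],
        specificity=params[f"specificity_{suffix}"],
        p_accept_referral=params[f"accept_referral_{suffix}"],
    )


def detection_probability(cfg: StrategyConfig, disease_present: bool = True) -> float:
    """Per-cycle probability that a person is screened, flagged, and follows
    up.  With disease present this uses sensitivity; without, it is the
    false-positive referral rate (no health-state effect, reportable only)."""
    flag = cfg.sensitivity if disease_present else 1.0 - cfg.specificity
    return cfg.p_accept_screening * flag * cfg.p_accept_referral


def treatment_entry_probability(cfg: StrategyConfig, stage: str,
                                params: ParameterSet) -> float:
    """Per-cycle probability that an untreated person in ``stage``
    (metabolic or ophthalmic) is detected and starts treatment."""
    try:
        adherence = params[_ADHERENCE_BY_STAGE[stage]]
    except KeyError:
        raise ParameterError(f"unknown disease stage {stage!r}") from None
    return detection_probability(cfg, disease_present=True) * adherence


def vision_loss_care_probability(params: ParameterSet) -> float:
    """Per-cycle probability that a person with symptomatic vision loss is
    under care: accepts the direct eye-care referral and adheres to
    vision-loss management.  Strategy-independent, since symptomatic vision
    loss bypasses screening."""
    return params["vl_accept_referral"] * params["adherence_vl"]
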