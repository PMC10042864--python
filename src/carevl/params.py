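"""Model parameter registry: definitions, validation, file round-trip.

Every quantity the model uses is a probability owned by this registry.
Each entry carries a base-case estimate plus the (low, high) range used
by the sensitivity analyses; ranges printed as open intervals in the
source literature are treated as closed for sweep endpoints.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "ParameterError",
    "CATEGORIES",
    "default_registry",
    "registry_by_name",
    "base_case",
    "rescale_probability",
    "load_parameters",
    "save_parameters",
    "registry_to_csv",
]

CATEGORIES = ("population", "diagnostic_accuracy", "process_of_care")


class ParameterError(ValueError):
    """Raised for unknown, missing, or out-of-range parameters."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model probability with its base case and sensitivity range."""

    name: str
    category: str
    base: float
    low: float
    high: float
    description: str = ""
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ParameterError(
                f"{self.name}: unknown category {self.category!r}"
            )
        if not 0.0 <= self.low <= self.base <= self.high <= 1.0:
            raise ParameterError(
                f"{self.name}: require 0 <= low <= base <= high <= 1, got "
                f"low={self.low}, base={self.base}, high={self.high}"
            )


@dataclass(frozen=True)
class ParameterSet(Mapping):
    """Immutable name -> probability mapping with a provenance tag."""

    values: dict[str, float]
    provenance: str = "base_case"

    def __post_init__(self) -> None:
        for name, value in self.values.items():
            if not 0.0 <= value <= 1.0:
                raise ParameterError(
                    f"{name}: value {value} outside [0, 1]"
                )

    def __getitem__(self, key: str) -> float:
        try:
            return self.values[key]
        except KeyError:
            raise ParameterError(f"unknown parameter {key!r}") from None

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def with_overrides(self, overrides: Mapping[str, float],
                       label: str | None = None) -> "ParameterSet":
        """New set with ``overrides`` applied; unknown names are errors."""
        for name in overrides:
            if name not in self.values:
                raise ParameterError(f"unknown parameter {name!r}")
        merged = dict(self.values, **overrides)
        tag = f"scenario:{label}" if label else "scenario:override"
        return ParameterSet(merged, provenance=tag if overrides else self.provenance)


def _specs() -> tuple[ParameterSpec, ...]:
    P, D, C = CATEGORIES
    return (
        # population: prevalence and natural history
        ParameterSpec("prevalence_metabolic", P, 0.22, 0.0, 0.40,
                      "Prevalence of metabolic DRD at enrollment"),
        ParameterSpec("prevalence_ophthalmic", P, 0.0088, 0.0, 0.10,
                      "Prevalence of ophthalmic DRD at enrollment",
                      "calculated value, source table footnote"),
        ParameterSpec("prevalence_vision_loss", P, 0.01, 0.0, 0.05,
                      "Prevalence of DRD with vision loss at enrollment"),
        ParameterSpec("no_drd_to_metabolic", P, 0.05, 0.0, 0.15,
                      "Annual transition, no DRD to metabolic DRD"),
        ParameterSpec("metabolic_to_ophthalmic", P, 0.02, 0.0, 0.20,
                      "Annual transition, untreated metabolic to ophthalmic DRD"),
        ParameterSpec("ophthalmic_to_vl", P, 0.075, 0.0, 0.20,
                      "Annual transition, untreated ophthalmic DRD to vision loss"),
        ParameterSpec("vl_to_irreversible", P, 0.37, 0.0, 0.50,
                      "Annual transition, untreated vision loss to irreversible vision loss"),
        # diagnostic accuracy
        ParameterSpec("sensitivity_ai", D, 0.87, 0.0, 1.0,
                      "Sensitivity of autonomous-AI screening for DRD"),
        ParameterSpec("sensitivity_ecp", D, 0.33, 0.0, 1.0,
                      "Sensitivity of eye-care-provider screening for DRD"),
        ParameterSpec("specificity_ai", D, 0.91, 0.0, 1.0,
                      "Specificity of autonomous-AI screening for DRD"),
        ParameterSpec("specificity_ecp", D, 0.99, 0.0, 1.0,
                      "Specificity of eye-care-provider screening for DRD"),
        # process of care: screening and referral
        ParameterSpec("accept_referral_ai", C, 0.75, 0.0, 0.95,
                      "Follows up for eye care after a positive AI screen"),
        ParameterSpec("accept_referral_ecp", C, 0.29, 0.0, 1.0,
                      "Follows up for eye exams after a positive ECP screen"),
        ParameterSpec("accept_screening_ai", C, 0.95, 0.0, 1.0,
                      "Accepts screening by autonomous AI"),
        ParameterSpec("accept_screening_ecp", C, 0.20, 0.0, 0.80,
                      "Accepts screening by an eye care provider"),
        ParameterSpec("vl_accept_referral", C, 0.58, 0.0, 0.75,
                      "Patient with vision loss accepts referral to eye care"),
        # process of care: effectiveness of treatments (treated progression)
        ParameterSpec("metabolic_to_ophthalmic_treated", C, 0.01, 0.0, 0.05,
                      "Annual transition, treated metabolic to ophthalmic DRD"),
        ParameterSpec("ophthalmic_to_vl_treated", C, 0.02, 0.0, 0.50,
                      "Annual transition, treated ophthalmic DRD to vision loss"),
        ParameterSpec("vl_to_irreversible_treated", C, 0.034, 0.0, 0.05,
                      "Annual transition, treated vision loss to irreversible vision loss"),
        # process of care: adherence to treatment
        ParameterSpec("adherence_metabolic", C, 0.24, 0.0, 1.0,
                      "Adheres to metabolic management"),
        ParameterSpec("adherence_ophthalmic", C, 0.26, 0.0, 1.0,
                      "Adheres to ophthalmic management",
                      "calculated value, source table footnote"),
        ParameterSpec("adherence_vl", C, 0.41, 0.0, 1.0,
                      "Adheres to vision-loss management",
                      "calculated value, source table footnote"),
    )


_REGISTRY = _specs()


def default_registry() -> tuple[ParameterSpec, ...]:
    """All model parameters with their published base/low/high values."""
    return _REGISTRY


def registry_by_name(
    registry: Iterable[ParameterSpec] | None = None,
) -> dict[str, ParameterSpec]:
    specs = tuple(registry) if registry is not None else _REGISTRY
    out: dict[str, ParameterSpec] = {}
    for spec in specs:
        if spec.name in out:
            raise ParameterError(f"duplicate parameter {spec.name!r}")
        out[spec.name] = spec
    return out


def base_case(registry: Iterable[ParameterSpec] | None = None) -> ParameterSet:
    """Base-case ParameterSet (every parameter at its point estimate)."""
    specs = registry_by_name(registry)
    return ParameterSet({n: s.base for n, s in specs.items()},
                        provenance="base_case")


def rescale_probability(p_cum: float, t_observed: float, t_cycle: float) -> float:
    """Convert a cumulative probability over ``t_observed`` years to one
    per ``t_cycle`` years assuming a constant hazard:
    ``1 - (1 - p)**(t_cycle / t_observed)``."""
    if not 0.0 <= p_cum <= 1.0:
        raise ParameterError(f"p_cum {p_cum} outside [0, 1]")
    if t_observed <= 0 or t_cycle <= 0:
        raise ParameterError("time spans must be positive")
    return 1.0 - (1.0 - p_cum) ** (t_cycle / t_observed)


def _validate_against_registry(values: Mapping[str, float],
                               registry: Iterable[ParameterSpec] | None) -> None:
    specs = registry_by_name(registry)
    unknown = set(values) - set(specs)
    if unknown:
        raise ParameterError(f"unknown parameter {sorted(unknown)[0]!r}")
    missing = set(specs) - set(values)
    if missing:
        raise ParameterError(f"missing parameter {sorted(missing)[0]!r}")
    for name, value in values.items():
        if not isinstance(value, (int, float)) or not 0.0 <= float(value) <= 1.0:
            raise ParameterError(f"{name}: value {value!r} outside [0, 1]")


def load_parameters(path: str | Path,
                    registry: Iterable[ParameterSpec] | None = None) -> ParameterSet:
    """Load a flat ``name: value`` parameter file (validated against the
    registry: no missing keys, no extras, all values in [0, 1])."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: expected a flat key-value mapping")
    provenance = str(raw.pop("provenance", "file"))
    _validate_against_registry(raw, registry)
    return ParameterSet({k: float(v) for k, v in raw.items()}, provenance)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter file that :func:`load_parameters` round-trips."""
    lines = [f"provenance: {params.provenance}"]
    lines += [f"{name}: {params[name]!r}" for name in sorted(params)]
    Path(path).write_text("\n".join(lines) + "\n")


def registry_to_csv(path: str | Path,
                    registry: Iterable[ParameterSpec] | None = None) -> None:
    """CSV export of the registry (name, category, base, low, high)."""
    specs = registry if registry is not None else _REGISTRY
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "category", "base", "low", "high", "description"])
        for s in specs:
            writer.writerow([s.name, s.category, s.base, s.low, s.high,
                             s.description])
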