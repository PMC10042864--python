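"""Cohort model: initial distribution, matrix structure, evolution."""

import numpy as np
import pytest

from carevl import (
    HealthState,
    ModelVariant,
    ParameterError,
    TransitionMatrix,
    any_vision_loss_per_100k,
    build_transition_matrix,
    initial_distribution,
    outcome,
    run_cohort,
    run_strategy,
    sample_parameter_sets,
    strategy_from_parameters,
)
from carevl.cohort import ModelStructureError

S = HealthState
# disease severity rank per state; transitions may never decrease it
_RANK = {S.NO_DRD: 0, S.MET_UNTX: 1, S.MET_TX: 1, S.OPH_UNTX: 2, S.OPH_TX: 2,
         S.VL_UNTX: 3, S.VL_TX: 3, S.IRREV_VL: 4}


def test_initial_distribution_seeds_prevalences(params):
    init = initial_distribution(params)  # default: vision loss counted
    assert init[S.MET_UNTX] == 0.22
    assert init[S.OPH_UNTX] == 0.0088
    assert init[S.VL_UNTX] == 0.01
    assert init[S.NO_DRD] == pytest.approx(1 - 0.22 - 0.0088 - 0.01)
    assert init.sum() == pytest.approx(1.0)

    excl = initial_distribution(params, include_vl_prevalence=False)
    assert excl.tolist() == pytest.approx(
        [0.7712, 0.22, 0, 0.0088, 0, 0, 0, 0])

    zero = params.with_overrides({"prevalence_metabolic": 0.0,
                                  "prevalence_ophthalmic": 0.0,
                                  "prevalence_vision_loss": 0.0})
    assert initial_distribution(zero)[S.NO_DRD] == 1.0


def test_initial_distribution_rejects_excess_prevalence(params):
    bad = params.with_overrides({"prevalence_metabolic": 0.8,
                                 "prevalence_ophthalmic": 0.4})
    with pytest.raises(ParameterError):
        initial_distribution(bad)


@pytest.mark.parametrize("strategy", ["no_screening", "ecp", "ai"])
def test_matrix_is_row_stochastic_and_forward_only(params, strategy):
    cfg = strategy_from_parameters(strategy, params)
    tm = build_transition_matrix(cfg, params)
    m = tm.matrix
    assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
    assert (m >= 0).all()
    for i in S:
        for j in S:
            if m[i, j] > 0:
                assert _RANK[j] >= _RANK[i], (i.name, j.name)
    # irreversible vision loss is absorbing
    assert m[S.IRREV_VL, S.IRREV_VL] == 1.0


def test_no_screening_vision_loss_entry_splits_by_care(params):
    cfg = strategy_from_parameters("no_screening", params)
    m = build_transition_matrix(cfg, params).matrix
    care = 0.58 * 0.41  # symptomatic vision-loss care probability
    assert m[S.OPH_UNTX, S.VL_TX] == pytest.approx(0.075 * care)
    assert m[S.OPH_UNTX, S.VL_UNTX] == pytest.approx(0.075 * (1 - care))


def test_zero_sensitivity_collapses_to_no_screening(params):
    blind = params.with_overrides({"sensitivity_ai": 0.0})
    ai = build_transition_matrix(strategy_from_parameters("ai", blind), blind)
    none = build_transition_matrix(
        strategy_from_parameters("no_screening", blind), blind)
    assert np.array_equal(ai.matrix, none.matrix)
    assert outcome("ai", blind) == outcome("no_screening", blind)


def test_strategy_symmetry(params):
    """Giving AI the ECP cascade makes the strategies indistinguishable."""
    sym = params.with_overrides({
        "accept_screening_ai": 0.20, "sensitivity_ai": 0.33,
        "specificity_ai": 0.99, "accept_referral_ai": 1.0,
    })  # ECP's effective cascade has no separate referral stage
    assert outcome("ai", sym) == pytest.approx(outcome("ecp", sym), abs=1e-12)


def test_run_cohort_identity_matrix(params):
    init = initial_distribution(params)
    identity = TransitionMatrix(np.eye(8), strategy="no_screening")
    trace = run_cohort(init, identity, 5)
    assert trace.occupancy.shape == (6, 8)
    assert np.allclose(trace.occupancy, init)


def test_run_cohort_rejects_bad_inputs(params):
    cfg = strategy_from_parameters("ai", params)
    tm = build_transition_matrix(cfg, params)
    with pytest.raises(ModelStructureError):
        run_cohort(np.zeros(5), tm, 5)
    with pytest.raises(ModelStructureError):
        run_cohort(initial_distribution(params), tm, -1)


@pytest.mark.parametrize("strategy", ["no_screening", "ecp", "ai"])
def test_vision_loss_occupancy_never_decreases(params, strategy):
    trace = run_strategy(strategy, params, horizon=5)
    vl = [trace.vision_loss(t) for t in range(6)]
    assert all(b >= a - 1e-12 for a, b in zip(vl, vl[1:]))
    assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)


def test_outcome_horizon_and_zero_cases(params):
    trace = run_strategy("ai", params, horizon=5)
    with pytest.raises(ModelStructureError):
        any_vision_loss_per_100k(trace, 6)
    frozen = params.with_overrides({
        "no_drd_to_metabolic": 0.0, "metabolic_to_ophthalmic": 0.0,
        "ophthalmic_to_vl": 0.0, "metabolic_to_ophthalmic_treated": 0.0,
        "ophthalmic_to_vl_treated": 0.0})
    no_vl = ModelVariant(count_vl_prevalence=False)
    assert outcome("ai", frozen, no_vl) == 0.0


def test_conservation_for_random_parameter_sets():
    for p in sample_parameter_sets(None, 100, seed=7):
        for strategy in ("no_screening", "ecp", "ai"):
            cfg = strategy_from_parameters(strategy, p)
            tm = build_transition_matrix(cfg, p)
            assert np.allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-12)


@pytest.mark.parametrize("adherence", [
    "adherence_metabolic", "adherence_ophthalmic", "adherence_vl"])
@pytest.mark.parametrize("strategy", ["ecp", "ai"])
def test_outcome_monotone_in_adherence(params, strategy, adherence):
    values = [outcome(strategy,
                      params.with_overrides({adherence: float(v)}))
              for v in np.linspace(0.0, 1.0, 11)]
    assert all(b <= a + 1e-9 for a, b in zip(values, values[1:]))


def test_matrix_construction_names_bad_cell(params):
    cfg = strategy_from_parameters("ai", params)
    tm = build_transition_matrix(cfg, params)
    broken = tm.matrix.copy()
    broken[1, 2] = 1.5
    with pytest.raises(ModelStructureError, match="MET_UNTX"):
        TransitionMatrix(broken, strategy="ai")
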