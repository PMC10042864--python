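"""Parameter registry: published values, conversion, file round-trip."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carevl import (
    ParameterError,
    ParameterSet,
    ParameterSpec,
    base_case,
    load_parameters,
    rescale_probability,
    save_parameters,
)
from carevl.params import registry_by_name, registry_to_csv

# the full published parameter table: name -> (category, base, low, high)
PUBLISHED = {
    "prevalence_metabolic": ("population", 0.22, 0.0, 0.40),
    "prevalence_ophthalmic": ("population", 0.0088, 0.0, 0.10),
    "prevalence_vision_loss": ("population", 0.01, 0.0, 0.05),
    "no_drd_to_metabolic": ("population", 0.05, 0.0, 0.15),
    "metabolic_to_ophthalmic": ("population", 0.02, 0.0, 0.20),
    "ophthalmic_to_vl": ("population", 0.075, 0.0, 0.20),
    "vl_to_irreversible": ("population", 0.37, 0.0, 0.50),
    "sensitivity_ai": ("diagnostic_accuracy", 0.87, 0.0, 1.0),
    "sensitivity_ecp": ("diagnostic_accuracy", 0.33, 0.0, 1.0),
    "specificity_ai": ("diagnostic_accuracy", 0.91, 0.0, 1.0),
    "specificity_ecp": ("diagnostic_accuracy", 0.99, 0.0, 1.0),
    "accept_referral_ai": ("process_of_care", 0.75, 0.0, 0.95),
    "accept_referral_ecp": ("process_of_care", 0.29, 0.0, 1.0),
    "accept_screening_ai": ("process_of_care", 0.95, 0.0, 1.0),
    "accept_screening_ecp": ("process_of_care", 0.20, 0.0, 0.80),
    "vl_accept_referral": ("process_of_care", 0.58, 0.0, 0.75),
    "metabolic_to_ophthalmic_treated": ("process_of_care", 0.01, 0.0, 0.05),
    "ophthalmic_to_vl_treated": ("process_of_care", 0.02, 0.0, 0.50),
    "vl_to_irreversible_treated": ("process_of_care", 0.034, 0.0, 0.05),
    "adherence_metabolic": ("process_of_care", 0.24, 0.0, 1.0),
    "adherence_ophthalmic": ("process_of_care", 0.26, 0.0, 1.0),
    "adherence_vl": ("process_of_care", 0.41, 0.0, 1.0),
}


def test_registry_is_exactly_the_published_table(registry):
    by_name = registry_by_name(registry)
    assert set(by_name) == set(PUBLISHED)
    for name, (category, base, low, high) in PUBLISHED.items():
        spec = by_name[name]
        assert (spec.category, spec.base, spec.low, spec.high) == \
            (category, base, low, high), name


def test_base_case_holds_every_parameter(registry, params):
    assert len(params) == len(PUBLISHED) == 22
    assert params.provenance == "base_case"
    assert all(0.0 <= params[n] <= 1.0 for n in params)
    single = base_case([registry[0]])
    assert len(single) == 1
    assert len(base_case([])) == 0


def test_spec_rejects_inverted_range():
    with pytest.raises(ParameterError):
        ParameterSpec("bad", "population", base=0.5, low=0.6, high=1.0)
    with pytest.raises(ParameterError):
        ParameterSpec("bad", "nonsense", base=0.5, low=0.0, high=1.0)


def test_set_rejects_out_of_range_and_unknown():
    with pytest.raises(ParameterError, match="foo"):
        ParameterSet({"foo": 1.3})
    with pytest.raises(ParameterError, match="nope"):
        base_case().with_overrides({"nope": 0.5})


@pytest.mark.parametrize("p_cum, t_obs, t_cyc, expected", [
    (0.0, 5.0, 1.0, 0.0),
    (1.0, 5.0, 1.0, 1.0),
    (0.10, 5.0, 1.0, 0.02085),  # 1 - 0.9 ** 0.2
])
def test_rescale_probability_closed_form(p_cum, t_obs, t_cyc, expected):
    assert rescale_probability(p_cum, t_obs, t_cyc) == pytest.approx(expected,
                                                                    abs=1e-5)


@settings(derandomize=True, max_examples=50)
@given(p=st.floats(0.0, 1.0), t=st.floats(0.1, 50.0))
def test_rescale_identity_at_equal_spans(p, t):
    assert rescale_probability(p, t, t) == pytest.approx(p, abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(p1=st.floats(0.0, 0.99), dp=st.floats(0.001, 0.01),
       t_cyc=st.floats(0.1, 5.0))
def test_rescale_monotone(p1, dp, t_cyc):
    a = rescale_probability(p1, 5.0, t_cyc)
    b = rescale_probability(min(p1 + dp, 1.0), 5.0, t_cyc)
    assert b >= a
    assert rescale_probability(p1, 5.0, t_cyc + 0.5) >= a


def test_rescale_rejects_bad_arguments():
    with pytest.raises(ParameterError):
        rescale_probability(1.2, 5.0, 1.0)
    with pytest.raises(ParameterError):
        rescale_probability(0.5, -1.0, 1.0)
    with pytest.raises(ParameterError):
        rescale_probability(0.5, 5.0, 0.0)


def test_parameter_file_round_trip(tmp_path, params):
    path = tmp_path / "params.yaml"
    save_parameters(params, path)
    loaded = load_parameters(path)
    assert dict(loaded) == dict(params)
    assert loaded.provenance == params.provenance


def test_load_rejects_out_of_range_value(tmp_path, params):
    path = tmp_path / "params.yaml"
    text = "\n".join(f"{n}: {params[n]}" for n in params)
    path.write_text(text.replace("sensitivity_ai: 0.87", "sensitivity_ai: 1.3"))
    with pytest.raises(ParameterError, match="sensitivity_ai"):
        load_parameters(path)


def test_load_rejects_missing_and_unknown_keys(tmp_path, params):
    path = tmp_path / "params.yaml"
    lines = [f"{n}: {params[n]}" for n in params if n != "adherence_vl"]
    path.write_text("\n".join(lines))
    with pytest.raises(ParameterError, match="adherence_vl"):
        load_parameters(path)
    path.write_text("\n".join(lines + ["adherence_vl: 0.41", "extra_key: 0.5"]))
    with pytest.raises(ParameterError, match="extra_key"):
        load_parameters(path)


def test_registry_csv_export(tmp_path, registry):
    path = tmp_path / "registry.csv"
    registry_to_csv(path, registry)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == len(registry) + 1
    assert lines[0].startswith("name,category,base,low,high")
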