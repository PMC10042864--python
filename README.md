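# carevl

A decision-analytic policy model of diabetic retinal disease (DRD)
screening. `carevl` implements an annual-cycle Markov cohort model that
compares three strategies for the diabetic eye exam among adults with
diabetes —

1. **no screening**,
2. **ECP screening**: in-clinic dilated exam by an eye care provider
   (ophthalmologist/optometrist), and
3. **autonomous-AI screening**: point-of-care fundus photography analyzed
   by an autonomous AI, with only positives referred to eye care —

on a single effectiveness outcome: the proportion of the cohort with any
vision loss at 5 years, reported per 100,000. The package is for health
services researchers and modelers who want to reproduce, stress-test, or
extend the comparison: it bundles the base-case analysis, one-way and
two-way sensitivity analyses with threshold search, maximal
process-of-care scenarios, population scaling, an individual-level
microsimulation oracle, and a structural-reconstruction harness.

## Model

Eight health states track disease severity and treatment status:

    NO_DRD → MET_UNTX/MET_TX → OPH_UNTX/OPH_TX → VL_UNTX/VL_TX → IRREV_VL

where MET is metabolic DRD (non-proliferative retinopathy, managed by
glycemic/blood-pressure/lipid control), OPH is ophthalmic DRD
(proliferative retinopathy or macular edema, needing ophthalmic
treatment), VL is vision loss, and IRREV_VL (absorbing) is irreversible
vision loss. Transitions never move backward.

A screening strategy enters the model through its care cascade. With
acceptance *a*, sensitivity *se*, and referral follow-up *r*, the
per-cycle probability that an untreated person with disease starts
stage-appropriate treatment is

    p(entry) = a · se · r · p(adherence_stage)

(for the ECP strategy the screen is itself an eye-care visit, so the
separate referral stage drops out). Treated states progress at the
treated ("effectiveness of treatment") rates while the person adheres,
and revert to natural-history rates otherwise. Symptomatic vision loss
bypasses screening: those patients enter care directly with probability
`p(accepts eye-care referral) · p(adheres to VL management)`.

The cohort starts at the published prevalences (metabolic 0.22,
ophthalmic 0.0088, vision loss 0.01) and is evolved 5 annual cycles; the
outcome is the combined occupancy of the vision-loss states, which equals
cumulative incidence because vision loss never reverts. All ~22 model
probabilities live in a single registry with base/low/high values
(`carevl.default_registry()`); every analysis works from an immutable
`ParameterSet`.

Because the source model's full decision tree is not public, the
structural choices it leaves open are explicit (`ModelVariant`) and a
harness (`carevl.scan_variants()`) ranks all 72 reconstructions against
the published base case; the package default is the closest one. See
`docs/methods.md` for the full account.

## Worked example

```python
from carevl import base_case, compare_strategies, round_half_up, scale_to_population

summary = compare_strategies(base_case())
for strategy, value in summary.outcomes.items():
    print(strategy, round_half_up(value))
diff = summary.risk_differences["ecp_minus_ai"]
print("AI prevents", scale_to_population(diff, 30_000_000), "more cases than ECP")
```

prints

```
no_screening 1637
ecp 1623
ai 1534
AI prevents 26829 more cases than ECP
```

i.e. at 5 years the model expects 1637 per 100,000 with any vision loss
without screening, 1623 with ECP screening, and 1534 with AI screening —
a risk difference of about 89 per 100,000 between the two active
strategies, which across 30 million Americans with diabetes is roughly
27,000 fewer people with vision loss. The `examples/` directory has one
short script per capability (base case, one-way/two-way sensitivity,
maximal scenarios, microsimulation cross-check, structural scan), each
printing its numbers with a line on what they mean. The same analyses are
available from the shell via the thin CLI:

```bash
carevl run --out results/
carevl sa --param accept_referral_ai --plot --out results/
carevl validate --n 100000 --seed 1 --out results/
```

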