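# Methods

## Model structure

`carevl` is a discrete-time state-transition (Markov) cohort model with a
1-year cycle and a 5-year horizon, evaluated without half-cycle
correction or discounting: the outcome is pure effectiveness (any vision
loss by 5 years), not cost or utility. The eight states are `NO_DRD`,
`MET_UNTX`, `MET_TX`, `OPH_UNTX`, `OPH_TX`, `VL_UNTX`, `VL_TX`, and the
absorbing `IRREV_VL`. Two structural invariants are enforced on every
constructed matrix: rows sum to one (1e-12) and no transition lowers the
disease-severity rank (vision loss never reverts), which is also why the
vision-loss occupancy at the horizon equals cumulative incidence.

Within a cycle, events follow decision-tree-before-Markov-node order:
the screening cascade is resolved first and decides which progression row
(treated or natural-history) the person draws that year. The same rules
drive both the cohort matrix and the microsimulation.

## Parameters

All quantities are annual probabilities held in a single registry, each
with a base case and a (low, high) sensitivity range; printed open
intervals are treated as closed for sweep endpoints. Multi-year
literature probabilities can be converted to per-cycle values with
`rescale_probability(p, t_observed, t_cycle) = 1 − (1 − p)^(t_cycle/t_observed)`
(constant hazard), but the registry defaults are stored as printed, at
annual scale.

| registry name | base (low–high) | meaning |
|---|---|---|
| `prevalence_metabolic` | 0.22 (0–0.40) | metabolic DRD at enrollment |
| `prevalence_ophthalmic` | 0.0088 (0–0.10) | ophthalmic DRD at enrollment |
| `prevalence_vision_loss` | 0.01 (0–0.05) | DRD with vision loss at enrollment |
| `no_drd_to_metabolic` | 0.05 (0–0.15) | natural history |
| `metabolic_to_ophthalmic` | 0.02 (0–0.20) | natural history |
| `ophthalmic_to_vl` | 0.075 (0–0.20) | natural history |
| `vl_to_irreversible` | 0.37 (0–0.50) | natural history |
| `sensitivity_ai` / `sensitivity_ecp` | 0.87 / 0.33 (0–1) | screening sensitivity |
| `specificity_ai` / `specificity_ecp` | 0.91 / 0.99 (0–1) | screening specificity |
| `accept_screening_ai` / `accept_screening_ecp` | 0.95 (0–1) / 0.20 (0–0.80) | accepts the exam |
| `accept_referral_ai` | 0.75 (0–0.95) | follows up after a positive AI screen |
| `accept_referral_ecp` | 0.29 (0–1) | follows up after a positive ECP screen |
| `vl_accept_referral` | 0.58 (0–0.75) | vision loss accepts direct eye-care referral |
| `metabolic_to_ophthalmic_treated` | 0.01 (0–0.05) | treated progression |
| `ophthalmic_to_vl_treated` | 0.02 (0–0.50) | treated progression |
| `vl_to_irreversible_treated` | 0.034 (0–0.05) | treated progression |
| `adherence_metabolic` | 0.24 (0–1) | adheres to metabolic management |
| `adherence_ophthalmic` | 0.26 (0–1) | adheres to ophthalmic management |
| `adherence_vl` | 0.41 (0–1) | adheres to vision-loss management |

False-positive referrals (screen-positive without disease,
`accept · (1 − specificity) · referral`) have no health-state effect and
are exposed only as a reportable rate: the model tracks effectiveness,
not harms or costs.

## Structural reconstruction and the variant harness

The source model's full decision tree (and its twelve assumptions) is in
a supplement that is not publicly available, so parts of the structure
had to be reconstructed from the published tables. The open choices are
explicit fields of `ModelVariant`, and `scan_variants()` evaluates all 72
combinations against the published base-case triple (1637 / 1625 / 1535
per 100,000). Three reconstruction findings drive the defaults:

1. **Prevalent vision loss is counted.** The no-screening outcome is
   reproduced essentially exactly (1636.98) only when the 0.01 prevalence
   of DRD-with-vision-loss is seeded into `VL_UNTX` and counted: about
   637 per 100,000 arise from incident disease over 5 years and 1000 from
   the prevalent pool.
2. **The ECP cascade has no separate referral stage.** The published
   threshold of 0.08 on the AI referral parameter pins the ECP detection
   product: 0.95 · 0.87 · 0.0799 ≈ 0.20 · 0.33. An ECP screen is already
   an eye-care visit, so a positive result needs no referral elsewhere;
   with the 0.29 follow-up factor included, the crossing would sit at
   0.023 and the ECP base case at ~1633 instead of the published 1625.
3. **Adherence is re-drawn every cycle.** The ECP benefit grows about
   12-fold when treatment adherence goes from base to 100%
   (1625 → 1488), which is superlinear in adherence and rules out
   permanently sticky treated status. In the default variant a treated
   person adheres each cycle with the stage's adherence probability
   (treated progression, stays treated) or lapses (natural-history
   progression, reverts to untreated and must be re-detected).

The remaining defaults, selected by the harness: the prevalent untreated
cohort is screened once at enrollment, with entry into care gated by
detection alone (diagnosis starts care; adherence then acts per cycle);
and progression out of a treated stage lands in the successor's
*untreated* substate — the next stage needs a different treatment, picked
up through the annual cascade. Under these choices the base triple
deviates at most 1.5 per 100,000 from the published values, and the
adherence-specific reductions under AI screening compute to 110 and 297
per 100,000 against published 110 and 294.

Known residual deviations, in line with the reconstruction uncertainty
and left visible as failing acceptance checks rather than patched: the
ECP maximal-adherence level computes to 1534 vs the published 1488
(3.1%), so the ECP both-adherence reduction is compressed (90 vs 137) and
the AI both-adherence reduction lands at 352 vs 367; and in the
metabolic-treatment-effectiveness sweep the AI preference flips in the
last 2% of the range (crossing ≈ 0.049; at the 0.05 endpoint "treatment"
progresses 2.5× faster than natural history) where the source reports AI
dominant throughout.

## Sensitivity and scenario analyses

One-way rows sweep a *model quantity*: where both strategies own a copy
of the parameter (acceptance, sensitivity, specificity), the sweep sets
both in lockstep to the common grid value — sweeping one strategy's
sensitivity alone to zero would collapse it to no screening and merely
restate that screening beats not screening. Sweeps default to 101 grid
points. The preferred strategy at a point is the one with strictly lower
vision loss; exact ties resolve toward AI and are flagged. Thresholds are
located by a 0.01-step grid scan for sign changes of the AI-minus-ECP
outcome difference, refined by Brent bisection to 1e-6 and reported at
two decimals; exact-zero stretches (ties) are not crossings. Two-way
analyses evaluate the preferred strategy over the full rectangle of both
ranges. Maximal scenarios re-run the model with process-of-care
parameters overridden (e.g. adherence = 1.0) and report each strategy's
change from its own base case. `scale_to_population` converts per-100,000
risk differences to persons (rounded half-up, as are all reported
per-100,000 figures; computations keep full precision).

## Microsimulation oracle

`simulate_individuals` replays the identical rule set as per-person
Bernoulli draws — acceptance, test result, follow-up, adherence,
progression, landing — with no shared code with the matrix construction,
so cohort/microsim agreement is a genuine implementation cross-check.
Draws are organized as a fixed block of uniforms per person-cycle (one
column per decision role), which makes runs with the same seed reuse
common random numbers across parameter values; the adherence
monotonicity check exploits this for variance reduction. Agreement is
assessed as a z-score against the binomial standard error; the default
validation size is 10^5 per run (keeping the test suite fast), the
acceptance check uses 10^6, and the bundled CLI flags comparisons with
fewer than ~30 expected events as underpowered.

`sample_parameter_sets` draws every registry parameter uniformly within
its (low, high) range; 1,000 such sets back the probability-conservation
property test. The generator emulates parameter uncertainty only — it is
not a probabilistic sensitivity analysis with calibrated distributions,
and the microsimulation population is exchangeable (no age structure,
inter-individual interaction, or covariates). Passing these checks shows
the two implementations encode the same process, not that the process
matches any particular real-world cohort.

## Limitations

No mortality, incident diabetes, or age structure (a closed cohort of
screened-eligible adults); vision loss in either eye, not the worse
eye; no costs, utilities, or QALYs; no telemedicine comparator; no
detection of non-DRD eye disease; screening is offered every cycle to
undiagnosed states only, and gradability failures are not modeled. The
published base-case triple and threshold structure are reproduced
closely, but the scenario-level deviations above mean conclusions that
hinge on the exact magnitude of the ECP maximal-adherence scenario
should be drawn with care.
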