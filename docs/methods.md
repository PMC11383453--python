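# Methods

## Model

`markovcea` implements a discrete-time Markov cohort model for two-strategy
cost-effectiveness comparisons, with a reference parameterization for
chronic heart-failure management under ACE inhibitors (comparator) versus
angiotensin receptor blockers (intervention).

The cohort moves across three health states — `Stable`, `Hospitalized` and
an absorbing `Dead` — in fixed cycles under a row-stochastic transition
matrix. The published model structure names only the two living states with
a hospitalization rate and a discharge rate between them; mortality rates
are nonetheless part of the input table, and mortality cannot enter a
two-state trace, so the package adds the absorbing `Dead` state. There is no
cure or remission: the chain is time-homogeneous, everyone in a state faces
the same transition probabilities (no covariates, no risk adjustment), and
transitions are booked at cycle boundaries.

Structural choices that the model structure itself leaves open:

* **Competing risks within a cycle.** Death is applied first; movement
  between living states applies conditionally to survivors. From `Stable`
  with per-cycle hospitalization probability `p_sh` and death probability
  `p_d`, the row is `((1−p_d)(1−p_sh), (1−p_d)·p_sh, p_d)`. This
  composition guarantees row sums of exactly 1 for any in-range inputs.
* **Rate rescaling.** Annual probabilities (hospitalization, death) are
  converted to the cycle length by `1 − (1 − p)^cl`, i.e. a constant hazard
  within the year. An annual probability of 1 cannot be rescaled and is
  rejected. Mortality inputs of 0.10/0.09 are read as **annual**: at a
  monthly reading the cohort would be essentially extinct within two years,
  inconsistent with a 5–10-year decision horizon.
* **Mortality is state-independent within a strategy** (the same annual
  probability applies in `Stable` and `Hospitalized`), because the input
  table prints one mortality rate per strategy. The engine accepts distinct
  values per state for users who have them.

## Parameter interpretation in the reference scenario

The published input table contains two rows, "transition probability"
0.70 and 0.65, whose labels ("ACE to ARB", "ARB to ACE") read like
treatment switching — a process the model structure does not contain. The
reference configuration therefore carries an explicit
`parameter_interpretation` block instead of a silent hard-coded guess; the
shipped interpretation reads them as the **per-cycle discharge probability**
(`Hospitalized → Stable`) under each strategy. Rationale: discharge is one
of the model's two named transitions, and 0.65–0.70 is a clinically
plausible monthly discharge probability, whereas it is implausible as an
annual hospitalization or mortality figure. Users who prefer another
reading edit the configuration, not the code.

The hospitalization rate (`Stable → Hospitalized`) is printed nowhere. The
reference scenario declares a structural default of **0.30 per year**,
shared by both strategies — a mid-range figure for symptomatic heart
failure cohorts — exposed in the configuration like every other parameter.

Quality of life while hospitalized is not printed either; the strategy
utilities (0.75 ACE, 0.77 ARB) are treated as the `Stable` state utility
and multiplied by a configurable decrement (default **0.80**) while
`Hospitalized`, reflecting the lower quality of life during an admission.
The multiplier is a first-class parameter and can be swept in sensitivity
analysis.

## Key parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| cycle length | 1/12 | years | monthly cycles |
| horizon | 120 cycles | — | 10 years |
| discount rate (costs, effects) | 0.03, 0.03 | /year | 0.05 as sensitivity; capped at 0.20 |
| medication cost | 50 | $/cycle | charged in both living states |
| hospitalization cost | 5000 | $/episode | charged on each entry into `Hospitalized` |
| annual hospitalization probability | 0.30 | /year | structural default, shared |
| per-cycle discharge probability | 0.70 / 0.65 | /cycle | ACE / ARB |
| annual mortality | 0.10 / 0.09 | /year | ACE / ARB |
| stable utility | 0.75 / 0.77 | — | ACE / ARB |
| hospitalized utility multiplier | 0.80 | — | applied to stable utility |

## Accounting

Person-time per state per cycle uses a **half-cycle (trapezoidal)
correction**: cycle *t* contributes `cl · (x[t−1] + x[t]) / 2`, crediting
transitions as happening mid-cycle on average. Costs per cycle are
state-time · per-cycle cost / cycle length, plus the per-episode cost times
the fraction newly entering `Hospitalized` that cycle (mass starting there
is charged one episode at time 0). QALYs are state-time · utility. Both
streams are discounted at end-of-cycle times with `(1+r)^(−t)`. Under
refinement of the cycle grid the trapezoidal totals converge to the
continuous-time integral; the test suite checks agreement within 1% against
a 10×-subdivided run whose matrix is the real 10th root of the cycle
matrix.

## Incremental analysis

ΔCost and ΔQALY are intervention minus comparator on discounted totals.
The ICER ΔC/ΔE is attached only in the trade-off quadrants (both
differences non-zero, same sign); the other quadrants are labelled
intervention-dominant, comparator-dominant or equal, with a zero ΔQALY and
non-zero ΔC classified as dominance by cost. For *tabulation*, the ratio is
reported whenever ΔE ≠ 0 and rounded half-up to the nearest dollar
(2400/0.09 → 26,667), with rounding confined to the reporting layer. Net
monetary benefit is `λ·ΔE − ΔC`; the CEAC reports, per willingness-to-pay
threshold, the fraction of PSA iterations with strictly positive NMB. Ties
(NMB exactly 0) go to the comparator — the lower-cost incumbent — which
shifts the curve by one sample weight and is therefore fixed and
documented. The default WTP grid is $0–$100,000 in $1,000 steps. With only
two strategies, extended dominance does not arise.

## Uncertainty

Each uncertain input is a (base, range, family) row. The range is read as a
**central 95% interval**, not hard bounds: the named families (beta, gamma,
normal) are support- or un-bounded, so moment matching needs a spread, and
sd = (high − low)/3.92. Families are fitted by moment inversion — beta:
ν = m(1−m)/σ² − 1, α = mν, β = (1−m)ν; gamma: shape m²/σ², scale σ²/m;
normal: (m, σ). Infeasible beta moments are rejected with the implied
(α, β) reported. A zero-width range degenerates to a point mass. Fitted
means reproduce the base values to well under 1e−6, and empirical 95%
intervals at n = 50,000 bracket the declared ranges.

PSA samples all parameters **independently** per iteration (no correlation
structure is declared anywhere), rebuilds both strategies, reruns the
engine and records the incremental result. A draw that violates a model
invariant (e.g. a normal cost going negative) is rejected and redrawn, with
a count kept, rather than truncated — truncation would distort the
families. Default n = 10,000, always seeded; identical seeds give
bit-identical output. One-way deterministic analysis reruns the model at a
parameter's bounds (the stock entry is drug cost ±25%: $37.50–$62.50) and
sorts entries by ICER swing for tornado reporting; discount-rate
sensitivity uses 3% and 5%.

## Synthetic data

No raw data accompany the analysis — the inputs are a parameter table — so
the synthetic module generates what testing needs:

* `random_scenario(seed, bounds)` draws valid scenarios uniformly within
  plausible chronic-heart-failure ranges (annual hospitalization 0.10–0.50,
  monthly discharge 0.40–0.90, annual mortality 0.02–0.20, medication
  $20–$100/month, episodes $2,000–$8,000, utilities 0.50–0.95, horizons
  24–120 months). Collapsing all bounds reproduces the reference values
  exactly.
* `simulate_individuals` realizes per-patient state sequences from a known
  transition matrix; `estimate_transitions` recovers the matrix by pooled
  row-wise maximum-likelihood counts (time-homogeneity pools transitions
  across cycles). Rows for states never observed as origins are flagged
  undetermined, not fabricated; Laplace smoothing is available but defaults
  to 0.

What the generators deliberately do **not** emulate: patient-level cost or
utility heterogeneity, covariate-dependent or time-varying transitions,
treatment switching, and adherence. Passing tests therefore demonstrate the
correctness of the machinery on data that satisfy the model's own
assumptions, not the adequacy of those assumptions for real heart-failure
cohorts.

## Numerical choices

* Row sums must hit 1 within 1e−12 at matrix construction and 1e−10 after
  propagation; occupancy agrees with the independent matrix-power oracle to
  1e−10 out to 240 cycles.
* Costs are kept at full precision internally, printed to cents in tables;
  QALYs printed to 4 decimals so that rounding is auditable.
* ICER rounding is half-up via decimal arithmetic, never float `round`.
* Problem sizes in the standard checks: 1,000 random scenarios for the
  engine oracle, 25 for refinement convergence, PSA at 2,000 draws in the
  reproduction script, recovery from 5,000 patients × 120 cycles (every
  cell recovered within ±0.02; observed ≈0.006).

## Known limitations

* The published mean costs/QALYs of the base-case table ($15,000/3.2 and
  $16,500/3.3) are **not derivable** from the published input table — the
  linkage is unstated — and the forward model makes no attempt to calibrate
  to them. The package reproduces that table's incremental arithmetic from
  its printed means, and separately reports the forward model's own
  incrementals from the input table (≈ +$534, +0.293 QALYs, ICER ≈
  $1,820/QALY for ARB vs ACE at base case).
* The printed age-subgroup rows both yield the base-case ICER while their
  ΔC/ΔE differ; the subgroup table reproduces the arithmetic and does not
  reconcile the narrative. Subgroup reproduction operates on printed
  (ΔC, ΔE) pairs; forward subgroup modelling is available only through
  user-defined parameter overrides, since no subgroup-specific inputs are
  published.
* Time-inhomogeneous matrices, tunnel states, >2-strategy frontiers and
  value-of-information analysis are out of scope.
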