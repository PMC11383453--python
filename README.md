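# markovcea

Markov cohort cost-effectiveness modelling for two-strategy treatment
comparisons, with a shipped reference scenario for chronic heart-failure
management: ACE inhibitors (comparator) versus angiotensin receptor
blockers (intervention).

The package is for health-economics practitioners and students who want a
small, fully tested decision-analytic pipeline: a discrete-time cohort
engine over `Stable` / `Hospitalized` / `Dead` states with half-cycle
correction and discounting; incremental analysis (ΔC, ΔE, ICER, dominance,
net monetary benefit); deterministic (tornado) and probabilistic
(Monte-Carlo) sensitivity analysis with cost-effectiveness acceptability
curves; validated YAML/JSON scenario files; and seeded synthetic-data
generators for property testing and parameter recovery.

## The model in brief

A cohort distribution `x_t` over states evolves as `x_t = x_{t-1} P` under
a row-stochastic per-cycle matrix `P` (monthly cycles, 120 by default).
Person-time uses the trapezoidal half-cycle correction
`cl · (x_{t-1} + x_t)/2`; costs (per-cycle medication plus per-episode
hospitalization on each `Hospitalized` entry) and QALYs (state utilities)
are discounted at `(1+r)^{-t}` with r = 3%/year. Strategies are compared by

ICER = ΔCost / ΔQALY,  NMB(λ) = λ·ΔQALY − ΔCost,

and the CEAC reports the fraction of PSA iterations with NMB(λ) > 0 over a
willingness-to-pay grid. Parameter uncertainty follows the conventional
input table: beta for probabilities and utilities, gamma for episode costs,
normal for drug costs, moment-matched so the mean equals the base value and
the printed range is a central 95% interval. See `docs/methods.md` for
assumptions, parameter interpretation and limitations.

## Worked example

```bash
markovcea base-case
```

```
Intervention  Mean costs ($)  Mean QALYs Mean difference in costs ($) Mean difference in QALYs ICER ($/QALY)
         ACE        12502.58      4.0790             N/A (Comparator)         N/A (Comparator)
         ARB        13036.13      4.3721                       533.55                   0.2931       1820.41
```

Over a 10-year horizon at 3% discounting, ACE therapy accrues $12,502.58
and 4.0790 QALYs per patient; ARBs cost $533.55 more and add 0.2931 QALYs
(lower mortality, higher utility, partly offset by a lower monthly
discharge probability), an ICER of $1,820.41 per QALY gained — a trade-off
well below conventional willingness-to-pay thresholds.

```bash
markovcea subgroups
```

```
                Subgroup  Incremental cost ($)  Incremental QALYs  Incremental cost-effectiveness ratio (ICER)
    Age group: <65 years                1200.0               0.08                                        15000
   Age group: >=65 years                1800.0               0.12                                        15000
  Disease severity: Mild                 800.0               0.10                                         8000
Disease severity: Severe                2400.0               0.09                                        26667
```

Each row divides the subgroup's incremental cost by its incremental QALYs
and rounds half-up to the dollar: both age bands land on $15,000/QALY,
while severity separates the strategies ($8,000 mild vs $26,667 severe).

Other commands: `markovcea psa` (seeded Monte-Carlo PSA + CEAC CSV),
`markovcea tornado` (one-way sensitivity, drug cost ±25% by default),
`markovcea simulate` / `markovcea estimate` (individual trajectories from a
strategy's matrix and maximum-likelihood recovery of the matrix from
them). Every command writes CSV outputs plus a JSON manifest recording the
inputs, seed and version. The same functionality is available as a library:

```python
from markovcea import reference_scenario, run_psa

scenario = reference_scenario()
print(scenario.run().incremental)
psa = run_psa(scenario, scenario.parameter_specs, n=10_000, seed=1)
print(psa.ceac().to_dataframe().head())
```

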