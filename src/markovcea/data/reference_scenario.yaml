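# Reference scenario: ACE inhibitors (comparator) vs ARBs (intervention)
# for chronic heart-failure management.  Markov cohort model with states
# Stable / Hospitalized / Dead, monthly cycles over a 10-year horizon,
# 3% annual discounting of costs and effects.
#
# parameter_interpretation documents how each published model-input row is
# bound to an engine role.  The two printed "transition probability" rows do
# not name a Stable/Hospitalized transition; this configuration reads them as
# the per-cycle discharge (Hospitalized -> Stable) probability under each
# strategy, the only printed probabilities of per-cycle magnitude for one of
# the model's two named transitions.  The hospitalization rate
# (Stable -> Hospitalized) is not printed anywhere; a structural default of
# 0.30 per year, shared by both strategies, is declared below.  Mortality
# rates are annual and are rescaled to the cycle length by the engine.
name: ace-vs-arb-heart-failure
description: >
  Two-strategy heart-failure comparison; medication $50/month, hospitalization
  $5000/episode, strategy utilities 0.75 (ACE) and 0.77 (ARB) with a 0.80
  multiplier while hospitalized.

plan:
  cycles_per_year: 12
  n_cycles: 120
  annual_discount_rate_costs: 0.03
  annual_discount_rate_effects: 0.03

parameter_interpretation:
  transition_probability_ace: comparator.p_discharge
  transition_probability_arb: intervention.p_discharge
  mortality_rate_ace: comparator.p_death_annual
  mortality_rate_arb: intervention.p_death_annual
  medication_cost_per_month: shared.medication_cost_per_cycle
  hospitalization_cost_per_episode: shared.hospitalization_cost_per_episode
  utility_value_ace_treated: comparator.utility_stable
  utility_value_arb_treated: intervention.utility_stable

strategies:
  comparator:
    name: ACE
    p_hospitalization_annual: 0.30
    p_discharge: 0.70
    p_death_annual: 0.10
    medication_cost_per_cycle: 50.0
    hospitalization_cost_per_episode: 5000.0
    utility_stable: 0.75
    hospitalized_utility_multiplier: 0.80
  intervention:
    name: ARB
    p_hospitalization_annual: 0.30
    p_discharge: 0.65
    p_death_annual: 0.09
    medication_cost_per_cycle: 50.0
    hospitalization_cost_per_episode: 5000.0
    utility_stable: 0.77
    hospitalized_utility_multiplier: 0.80

parameters:
  - name: transition_probability_ace
    base: 0.70
    low: 0.60
    high: 0.80
    family: beta
    units: probability/cycle
    targets: [comparator.p_discharge]
  - name: transition_probability_arb
    base: 0.65
    low: 0.55
    high: 0.75
    family: beta
    units: probability/cycle
    targets: [intervention.p_discharge]
  - name: mortality_rate_ace
    base: 0.10
    low: 0.08
    high: 0.12
    family: beta
    units: probability/year
    targets: [comparator.p_death_annual]
  - name: mortality_rate_arb
    base: 0.09
    low: 0.07
    high: 0.11
    family: beta
    units: probability/year
    targets: [intervention.p_death_annual]
  - name: medication_cost_per_month
    base: 50.0
    low: 45.0
    high: 55.0
    family: normal
    units: USD/month
    targets: [shared.medication_cost_per_cycle]
  - name: hospitalization_cost_per_episode
    base: 5000.0
    low: 4500.0
    high: 5500.0
    family: gamma
    units: USD/episode
    targets: [shared.hospitalization_cost_per_episode]
  - name: utility_value_ace_treated
    base: 0.75
    low: 0.70
    high: 0.80
    family: beta
    units: utility
    targets: [comparator.utility_stable]
  - name: utility_value_arb_treated
    base: 0.77
    low: 0.72
    high: 0.82
    family: beta
    units: utility
    targets: [intervention.utility_stable]
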