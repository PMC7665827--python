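# Default analysis configuration: the 2012-2016 maternal/newborn
# systems-strengthening program at a regional referral hospital in
# Accra, Ghana.  All values are configurable.

baseline_year: 2012

demography:
  age_at_death: 0.0192            # years; early neonatal deaths dominate
  life_expectancy: 62.5           # years; Ghana life expectancy at birth
  stillbirth_age: 0.0             # a stillborn's age at the event is zero
  stillbirth_life_expectancy: 62.5

social_value:
  discount_rate: 0.03             # r, per year (WHO standard)
  age_weight_K: 1.0               # K in [0, 1]; 0 disables age weighting
  age_weight_beta: 0.04           # beta, per year
  age_weight_C: 0.1658            # normalization constant of the age weight

thresholds:
  gdp_per_capita: 1649            # Ghana, average per-capita GDP 2012-2016, US$
  league_income_level: middle     # league-table cutoffs: middle-income country

costing:
  include_nicu_renovation: false  # omitted 4,980.28 US$ renovation line

psa:
  n_draws: 10000
  seed: 2016
  se_convention: sample           # sample | poisson | binomial
  vary:
    age_relative: 0.10            # uniform +/-10% around age at death
    life_expectancy_relative: 0.10
    professional_time_relative: 0.25

tornado:
  min_contribution: 0.04          # suppress bars under 4% in the report
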