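tree:
  p_death_procedure: 0.022
  p_death_maturation: 0.054
  p_mature_functional: 0.772
  p_death_nonmaturation: 0.011
  p_cvc_nonmaturation: 0.065
  p_functional_after_intervention: 0.076
  cost_placement: 4641.19
  cost_revision: 4593.26
  cost_cvc_placement: 896.97
markov:
  p_functional_to_functional: 0.932
  p_functional_to_failed: 0.057
  p_functional_to_dead: 0.011
  p_failed_to_functional: 0.533
  p_failed_to_failed: 0.28
  p_failed_to_cvc: 0.12
  p_failed_to_dead: 0.067
  p_cvc_to_cvc: 0.974
  p_cvc_to_dead: 0.026
  utility_functional: 0.6839
  utility_failed: 0.5939
  utility_cvc: 0.6526
  cost_failed_monthly: 647.62
  cost_cvc_monthly: 2730.18
econ:
  annual_discount_rate: 0.03
  wtp_lambda: 100000.0
  horizon_cycles: 60
  cycle_length_months: 1
  accrual: start
  discounting: annual
  tree_cvc_enters_markov: true
stages:
- name: Concept Development
  cost: 12277791.0
  p_success: 0.7775
  duration_years: 3.0
  start_elapsed_years: 0.0
- name: Clinical Unit Development
  cost: 11050012.0
  p_success: 0.7775
  duration_years: 2.0
  start_elapsed_years: 3.0
- name: IDE Application
  cost: 13505570.0
  p_success: 0.7775
  duration_years: 1.0
  start_elapsed_years: 5.0
- name: Clinical Safety Study
  cost: 11050012.0
  p_success: 0.48
  duration_years: 1.0
  start_elapsed_years: 6.0
- name: Pivotal Clinical Trial
  cost: 50338943.0
  p_success: 0.757
  duration_years: 3.0
  start_elapsed_years: 7.0
- name: PMA Approval Process
  cost: 17188907.0
  p_success: 0.805
  duration_years: 2.0
  start_elapsed_years: 10.0
market:
  years:
  - year: 2035
    market_size: 21195.0
    penetration: 0.15
  - year: 2036
    market_size: 21300.0
    penetration: 0.3
  - year: 2037
    market_size: 21403.0
    penetration: 0.45
  - year: 2038
    market_size: 21504.0
    penetration: 0.6
  - year: 2039
    market_size: 21602.0
    penetration: 0.75
  - year: 2040
    market_size: 21698.0
    penetration: 0.75
  - year: 2041
    market_size: 21793.0
    penetration: 0.75
  - year: 2042
    market_size: 21885.0
    penetration: 0.75
  - year: 2043
    market_size: 21976.0
    penetration: 0.75
  - year: 2044
    market_size: 22066.0
    penetration: 0.75
commercial:
  cogs_per_unit: 100.0
  sga_fraction_of_revenue: 0.3
  ococ_discount_rate: 0.104
  base_year: 2023
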