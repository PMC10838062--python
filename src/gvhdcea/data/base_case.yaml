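# Base-case model specification: extracorporeal photopheresis (ECP) vs
# survey-weighted standard-of-care immunosuppression for steroid-refractory
# chronic graft-vs-host disease.  All currency values are 2021 AUD.
#
# The `evidence` block carries the upstream summary statistics; the
# `probabilities` block carries the published per-cycle transition
# probabilities that parameterize the chain.  `gvhdcea derive` compares the
# two layers.

metadata:
  label: ECP vs weighted SoC, steroid-refractory cGVHD (Australia, 2021 AUD)
  currency: AUD 2021

evidence:
  ecp_response_week12: 0.802
  rr_response_ecp_vs_soc: 3.95
  responder_mortality_cum: 0.20
  nonresponder_mortality_cum: 0.53
  followup_weeks: 208.0
  median_treatment_weeks: 37.0
  responder_progression_cum: 0.041
  progression_ref_weeks: 52.0
  frac_death_respiratory: 0.55
  cycle_weeks: 12.0

probabilities:
  progression_responders_annual: 0.041
  progression_ref_weeks: 52.0
  p_death_responder_per_cycle: 0.013
  p_death_progressed_per_cycle: 0.042
  p_discontinue_per_cycle: 0.201
  frac_death_respiratory: 0.55

costs:
  ecp_cycle1: 52932.0
  ecp_maintenance: 12704.0
  soc_components:
    - {label: mycophenolate, cost: 349.0, weight: 0.44}
    - {label: tacrolimus, cost: 5258.0, weight: 0.23}
    - {label: cyclosporin, cost: 1987.0, weight: 0.33}
  prednisone_start: 92.0
  prednisone_down: 42.0
  subsequent_therapy: 5793.0
  progression_event: 4324.0
  infection_hospitalization: 562.0
  death_respiratory_event: 21061.0
  management_response: 309.0
  management_progressed: 7147.0

utilities:
  u_response: 0.786
  u_progressed: 0.696
  u_dead: 0.0

settings:
  horizon_cycles: 44
  cycle_length_weeks: 12.0
  annual_discount_rate: 0.05
  wtp_threshold: 50000.0
  weeks_per_year: 52.0
  half_cycle_correction: true

# PSA distribution families follow the published input table: beta for
# probabilities, lognormal for the relative risk, utilities and unit costs;
# `fixed` rows are listed for completeness and never varied.  Spreads are
# not published; the default standard error is 20% of the base value
# (spread_frac 0.2), overridable per parameter.
psa:
  - {path: evidence.ecp_response_week12, family: beta}
  - {path: evidence.rr_response_ecp_vs_soc, family: lognormal}
  - {path: probabilities.progression_responders_annual, family: beta}
  - {path: probabilities.p_death_responder_per_cycle, family: beta}
  - {path: probabilities.p_death_progressed_per_cycle, family: beta}
  - {path: probabilities.p_discontinue_per_cycle, family: beta}
  - {path: utilities.u_response, family: lognormal, upper: 1.0}
  - {path: utilities.u_progressed, family: lognormal, upper: 1.0}
  - {path: costs.soc_components.mycophenolate, family: lognormal}
  - {path: costs.soc_components.tacrolimus, family: lognormal}
  - {path: costs.soc_components.cyclosporin, family: lognormal}
  - {path: costs.subsequent_therapy, family: lognormal}
  - {path: costs.progression_event, family: lognormal}
  - {path: costs.infection_hospitalization, family: lognormal}
  - {path: costs.management_response, family: lognormal}
  - {path: costs.management_progressed, family: lognormal}
  - {path: costs.ecp_cycle1, family: fixed}
  - {path: costs.ecp_maintenance, family: fixed}
  - {path: costs.prednisone_start, family: fixed}
  - {path: costs.prednisone_down, family: fixed}
  - {path: costs.death_respiratory_event, family: fixed}
  - {path: probabilities.frac_death_respiratory, family: fixed}
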