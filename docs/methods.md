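# Methods

## Model structure and assumptions

The model is a deterministic Markov cohort simulation with four states:
response on treatment, response off treatment, progressed disease, and
dead. It deliberately mirrors the published Australian evaluation of
extracorporeal photopheresis (ECP) for steroid-refractory chronic
graft-vs-host disease: a 12-week cycle, a 44-cycle (10-year) horizon, 5%
annual discounting, costs in 2021 AUD, and cohort-level accrual (no
patient-level heterogeneity, tunnel states, or time-varying hazards beyond
the induction/maintenance distinction).

Cycle 1 is the induction cycle. The whole cohort is on treatment until
the week-12 response assessment at the end of the cycle, which splits it
into responders (remain in response on treatment) and progressors. No
death or discontinuation is applied during induction: the published
evidence reports the week-12 split directly, and applying additional
induction-phase risks would distort it. From cycle 2 onward, competing
transitions within a cycle are treated as mutually exclusive raw
probabilities with the residual mass remaining in state (they sum to
about 0.26 from the response states, so the residual is always
well-defined; a spec whose outgoing probabilities exceed 1 is rejected,
never renormalized). Off-treatment responders carry the same progression
and mortality risks as on-treatment responders, and there is no route
back onto treatment or out of progression except death.

## Parameter derivation

Per-cycle probabilities are derived from the published summary evidence by
constant-hazard (exponential) conversion:

- mortality: cumulative 20% (responders) and 53% (non-responders) over the
  4-year (208-week) median follow-up give
  `1 − (1 − p)^(12/208)` = 0.0128 and 0.0426 per cycle;
- discontinuation: the 37-week median treatment duration gives
  `1 − 0.5^(12/37)` = 0.2013 per cycle (geometric survival with that
  median);
- the comparator's week-12 progression follows from the relative risk of
  response: `1 − 0.802/3.95` = 0.797.

The source material describes the mortality conversion as "assuming a
linear function", but only the constant-hazard form recovers the published
per-cycle values from the quoted summary statistics; a proportional
(`linear`) alternative is available in `rescale_probability` for
transparency.

Two published values deserve comment. First, the published per-cycle
non-responder mortality is 0.042 while the conversion of the rounded 53%
cumulative input yields 0.0426; the published cumulative figure is itself
rounded (a true cumulative mortality anywhere in 52–53% reproduces 0.042),
so the derivation is checked to within one unit in the last printed digit
for this value. Second, the responders' progression risk is published as
0.041 "per cycle" in the input table, while the accompanying text states
the per-cycle risk "was calculated to be 1%". Used directly per cycle,
0.041 is irreconcilable with the published incremental results (it roughly
triples the progression hazard and inverts the sign of the incremental
cost); interpreted as an annual cumulative risk and rescaled to the
12-week cycle it gives `1 − 0.959^(12/52)` = 0.0096 ≈ 1%, consistent with
the text and with the published totals. The package therefore stores
progression as an annual probability with a 52-week reference period and
rescales it per cycle.

The chain itself is parameterized by the per-cycle probabilities as
published (0.013, 0.042, 0.201), transcribed in the packaged spec file;
the derivation layer independently recomputes each of them from the
upstream evidence, and the `derive` report shows the comparison. This
separation means the published model's inputs drive the results while
every one of them remains reproducible from first principles.

## Costing and accrual conventions

State costs per cycle: on-treatment response accrues the arm's treatment
cost (ECP induction course $52,932 in cycle 1, maintenance $12,704
thereafter; the survey-weighted immunosuppressant blend
0.44·349 + 0.23·5258 + 0.33·1987 = $2,018.61 for the comparator every
cycle), prednisone (start dose $92 in cycle 1, down-titrated $42
afterwards), and responder disease management ($309). Off-treatment
response accrues management plus down-titrated prednisone only.
Progression accrues subsequent (third-line) therapy ($5,793), progressed
disease management ($7,147) and the prednisone start dose. One-off event
costs attach to flows: $4,324 + $562 (progression event plus infection
admission) on each entry into the progressed state, and $21,061 on the
55% of progressed-to-dead transitions attributed to respiratory failure.
The infection admission is charged once on entry, not per cycle in the
state, following the description of its attribution "when patients
transition".

Discounting uses fractional-year exponents with 52-week years:
cycle *c* accruals are multiplied by `1.05^(−(c−1)·12/52)`, so the first
cycle is undiscounted.

Recurring state costs and utilities accrue on the **average of start- and
end-of-cycle occupancy** (half-cycle correction), exposed as the
`half_cycle_correction` run setting. The single exception is the ECP
induction course in cycle 1: it is a fixed, front-loaded course (three
treatments in week 1, then two per week to week 12) delivered in full to
every patient who starts it, irrespective of the response assessment at
the end of the cycle, so it is charged to the full start-of-cycle cohort —
week-12 non-responders still incur it. The comparator's drug costs are
dispensed continuously and are half-cycle corrected like other recurring
costs. These conventions are the package's reading of the published
model's unstated cycle accounting; with them, all six published summary
cells (per-arm costs and QALYs, incremental cost and QALYs) are reproduced
within 2.5%, and both QALY totals within 0.8%.

QALYs use utility 0.786 in both response states, 0.696 in progression, 0
when dead, scaled by 12/52 year per cycle.

## Sensitivity analysis

One-way analysis re-runs the full pipeline with a single spec field
replaced; anything derived from that field (the comparator induction
split, the per-cycle progression, the weighted drug blend) is re-derived
automatically because evaluation always starts from the spec. Default
ranges are ±20% of the base value (the published tornado's ranges are not
reported); bars are sorted by the width of the net-monetary-benefit
interval. Utility ordering (progressed ≤ response) is deliberately not
enforced during sensitivity runs — pushing the progressed utility above
the response utility is a meaningful what-if — while range checks
(probabilities in [0, 1], non-negative costs) still apply.

The PSA assigns beta distributions to probabilities and lognormal
distributions to the relative risk, utilities and unit costs, matching the
published distribution-family table; parameters marked "not varied" are
fixed. The published analysis does not report distribution spreads, so
exact reproduction of its 98% probability and ICER percentiles is not
possible; the package defaults to a standard error of 20% of the base
value for every varied parameter, overridable per parameter in the spec
file. Utility draws are truncated at 1.0 (declared as an `upper` bound in
the spec); draws are independent, as no correlation structure is
described. Iteration *i* of a run seeded with *s* uses the dedicated
substream `default_rng([s, i])`, making results independent of execution
order and bit-reproducible. ICER percentiles (2.5th/97.5th) are computed
over the raw per-iteration ratio ΔC/ΔE, excluding (and counting)
iterations with |ΔE| below a 1e-6 QALY floor to avoid division blow-ups.
Because roughly 2% of draws lose QALYs under these spreads, the
acceptability curve computed over all iterations can dip by a fraction of
a percentage point; it is monotone over the QALY-gaining subset, which is
the property the test suite asserts.

## Synthetic model generator

Property tests run against randomly generated model specs
(`gvhdcea.synthetic`). The generator keeps the fixed four-state topology
(the costing rules are topology-specific by design) and draws every
numeric input at random: per-cycle probabilities first, under a cap
(default 0.6) on each state's outgoing sum, then the evidence layer by
inverting the derivation closed forms, so the stated and derived parameter
layers agree exactly and every generated spec passes the same validation
as a user-supplied file. Costs are uniform on [0, 50,000], utilities
ordered uniform draws, horizons 4–30 cycles, discount rates 0–10%, and
half-cycle correction is toggled at random. Generation is deterministic
in (seed, index).

The generator emulates the *structural* assumptions of the analysis —
absorbing death, induction split, competing per-cycle risks, non-negative
costs, ordered utilities — not the joint distribution of real cGVHD
evidence: generated parameter combinations can be clinically implausible
(e.g. progression cheaper than response). Passing property tests
therefore certify the engine's arithmetic (conservation, absorbing-state
monotonicity, oracle agreement, discount identities, cost linearity) on
arbitrary valid inputs, not the clinical realism of any particular spec.

## Verification

The deterministic engine is cross-validated against an independent
individual-level microsimulation (`microsim_oracle`) that draws each
patient's path from the same per-cycle transition rows: on 20 generated
models, cohort occupancies agree with a 100,000-patient simulation within
4 binomial standard errors at every cycle. The invariant suite runs on
1,000 generated models. Problem sizes (20 × 100,000 paths; 1,000 models;
1,000 PSA iterations) were chosen to keep the full test suite around ten
seconds while leaving Monte-Carlo tolerances comfortably non-flaky.

## Known limitations

- The upstream calibration of the week-12 response and progression rates
  from registry data (a "natural logarithmic function" fit) is not
  reproducible from published information; those values are consumed as
  given.
- Published summary results are reproduced within 2.5%, not exactly: the
  original TreeAge implementation's cycle accounting is not fully
  specified, and the residual conventions (exact treatment of the
  induction cycle, rounding of intermediate values) cannot be recovered
  from the publication.
- The PSA's published summary statistics (98% probability cost-effective,
  ICER percentiles of −$45,446 and $74,626) depend on unreported
  distribution spreads and are treated as qualitative anchors only; with
  the default 20% spreads this implementation obtains ≈97% and percentiles
  of the same sign and order of magnitude.
- No half-cycle correction variant of the published model can be ruled
  in or out; both conventions are available via `half_cycle_correction`.
- Single currency (2021 AUD), healthcare-payer perspective; no EVPI,
  correlated sampling, or adverse-event disutilities.
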