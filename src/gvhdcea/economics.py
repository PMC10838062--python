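"""Cost and QALY accrual over a cohort trace, discounting, and ICER summaries.

Costing rules
-------------
* ``RESPONSE_ON_TREATMENT`` accrues the arm's treatment cost (the
  photopheresis induction course in cycle 1 and maintenance thereafter for
  the intervention arm; the survey-weighted immunosuppressant blend every
  cycle for the comparator), prednisone (start dose in cycle 1,
  down-titrated dose afterwards) and responder disease-management costs.
* ``RESPONSE_OFF_TREATMENT`` accrues responder management plus
  down-titrated prednisone only — patients keep their response but no
  longer accumulate second-line treatment costs.
* ``PROGRESSED`` accrues subsequent (third-line) therapy, progressed-state
  management, and the prednisone start dose.
* One-off event costs attach to transition flows: a progression event cost
  plus an infection-hospitalization cost on every entry into
  ``PROGRESSED``, and a terminal-hospitalization cost on the fraction of
  progressed-to-dead transitions attributed to respiratory failure.

Cycle accounting
----------------
Recurring state costs and utilities accrue on the average of start- and
end-of-cycle occupancy when ``half_cycle_correction`` is enabled
(start-of-cycle occupancy otherwise).  The induction treatment course is
the exception: it is a fixed, front-loaded course delivered in full to
every patient who starts it, irrespective of the response assessment at
the end of the cycle, so it is charged to the full start-of-cycle cohort.
Cycle ``c`` accruals are discounted by the factor for ``c - 1`` elapsed
cycles (the first cycle is undiscounted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ArmParameters, CohortTrace, HealthState, RunSettings

__all__ = [
    "SocComponent",
    "CostInputs",
    "UtilityInputs",
    "ArmOutcome",
    "EconResult",
    "discount_factor",
    "weighted_soc_cost",
    "treatment_cost",
    "state_cost_per_cycle",
    "event_costs",
    "accrue",
    "compare",
]

ECP_ARM = "ECP"


@dataclass
class SocComponent:
    label: str
    cost: float
    weight: float


@dataclass
class CostInputs:
    """Per-cycle state costs and one-off event costs, in 2021 AUD."""

    ecp_cycle1: float = 52_932.0
    ecp_maintenance: float = 12_704.0
    soc_components: list[SocComponent] = field(
        default_factory=lambda: [
            SocComponent("mycophenolate", 349.0, 0.44),
            SocComponent("tacrolimus", 5_258.0, 0.23),
            SocComponent("cyclosporin", 1_987.0, 0.33),
        ]
    )
    prednisone_start: float = 92.0
    prednisone_down: float = 42.0
    subsequent_therapy: float = 5_793.0
    progression_event: float = 4_324.0
    infection_hospitalization: float = 562.0
    death_respiratory_event: float = 21_061.0
    management_response: float = 309.0
    management_progressed: float = 7_147.0

    def validate(self) -> list[str]:
        errors = []
        for name in (
            "ecp_cycle1",
            "ecp_maintenance",
            "prednisone_start",
            "prednisone_down",
            "subsequent_therapy",
            "progression_event",
            "infection_hospitalization",
            "death_respiratory_event",
            "management_response",
            "management_progressed",
        ):
            v = getattr(self, name)
            if v < 0:
                errors.append(f"costs.{name}={v!r} must be non-negative")
        for comp in self.soc_components:
            if comp.cost < 0:
                errors.append(f"costs.soc_components.{comp.label}.cost={comp.cost!r} negative")
            if comp.weight < 0:
                errors.append(
                    f"costs.soc_components.{comp.label}.weight={comp.weight!r} negative"
                )
        wsum = sum(c.weight for c in self.soc_components)
        if abs(wsum - 1.0) > 1e-9:
            errors.append(f"costs.soc_components weights sum to {wsum!r}, expected 1")
        return errors


@dataclass
class UtilityInputs:
    """Health-state utility weights (dead fixed at 0 by convention)."""

    u_response: float = 0.786
    u_progressed: float = 0.696
    u_dead: float = 0.0

    def validate(self, ordering: bool = True) -> list[str]:
        """Range checks, plus the dead <= progressed <= response ordering.

        Sensitivity analyses relax ``ordering``: a one-way variation may
        legitimately push the progressed-state utility above the response
        utility, which is a meaningful what-if rather than a spec error.
        """
        errors = []
        for name in ("u_response", "u_progressed", "u_dead"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"utilities.{name}={v!r} outside [0, 1]")
        if ordering and not errors:
            if not self.u_dead <= self.u_progressed <= self.u_response:
                errors.append(
                    "utilities must satisfy u_dead <= u_progressed <= u_response, got "
                    f"({self.u_dead!r}, {self.u_progressed!r}, {self.u_response!r})"
                )
        return errors

    def as_vector(self) -> np.ndarray:
        return np.array([self.u_response, self.u_response, self.u_progressed, self.u_dead])


@dataclass(frozen=True)
class ArmOutcome:
    arm_name: str
    cost: float
    qaly: float


@dataclass(frozen=True)
class EconResult:
    """Incremental cost-utility summary of intervention vs comparator."""

    intervention: ArmOutcome
    comparator: ArmOutcome
    delta_cost: float
    delta_qaly: float
    classification: str  # "dominant" | "dominated" | "icer" | "equal_effects"
    icer: float | None
    nmb_at_wtp: float
    wtp_threshold: float


def discount_factor(cycle_index: int, settings: RunSettings) -> float:
    """Discount factor after ``cycle_index`` elapsed cycles (fractional years)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    years = cycle_index * settings.cycle_years
    return float((1.0 + settings.annual_discount_rate) ** (-years))


def weighted_soc_cost(components: list[SocComponent]) -> float:
    """Survey-weighted per-cycle cost of the comparator drug blend."""
    wsum = sum(c.weight for c in components)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"component weights sum to {wsum!r}, expected 1")
    return sum(c.cost * c.weight for c in components)


def treatment_cost(arm_name: str, cycle_index: int, costs: CostInputs) -> float:
    """Second-line treatment cost for a cycle spent on treatment."""
    if arm_name == ECP_ARM:
        return costs.ecp_cycle1 if cycle_index == 1 else costs.ecp_maintenance
    return weighted_soc_cost(costs.soc_components)


def state_cost_per_cycle(
    state: HealthState,
    arm_name: str,
    cycle_index: int,
    costs: CostInputs,
    include_treatment: bool = True,
) -> float:
    """Recurring cost of one cycle spent in ``state``.

    ``include_treatment=False`` returns the non-treatment component only
    (used by the accrual loop, which charges the induction treatment
    course on a different occupancy basis).
    """
    s = HealthState(state)
    if s is HealthState.DEAD:
        return 0.0
    if s is HealthState.RESPONSE_ON_TREATMENT:
        prednisone = costs.prednisone_start if cycle_index == 1 else costs.prednisone_down
        base = prednisone + costs.management_response
        if include_treatment:
            base += treatment_cost(arm_name, cycle_index, costs)
        return base
    if s is HealthState.RESPONSE_OFF_TREATMENT:
        return costs.management_response + costs.prednisone_down
    return costs.subsequent_therapy + costs.management_progressed + costs.prednisone_start


def event_costs(
    flow_matrix: np.ndarray, params: ArmParameters, costs: CostInputs
) -> float:
    """One-off costs attached to this cycle's transition flows."""
    prog = int(HealthState.PROGRESSED)
    dead = int(HealthState.DEAD)
    entries = flow_matrix[:, prog].sum() - flow_matrix[prog, prog]
    progression = entries * (costs.progression_event + costs.infection_hospitalization)
    respiratory = (
        flow_matrix[prog, dead]
        * params.frac_death_respiratory
        * costs.death_respiratory_event
    )
    return float(progression + respiratory)


def accrue(
    trace: CohortTrace,
    costs: CostInputs,
    utilities: UtilityInputs,
    settings: RunSettings,
    arm_name: str,
    params: ArmParameters,
) -> ArmOutcome:
    """Discounted total cost and QALYs for one arm over the horizon."""
    if trace.horizon != settings.horizon_cycles:
        raise ValueError(
            f"trace horizon {trace.horizon} != settings.horizon_cycles "
            f"{settings.horizon_cycles}"
        )
    occ = trace.occupancy
    on = int(HealthState.RESPONSE_ON_TREATMENT)
    u = utilities.as_vector()
    total_cost = 0.0
    total_qaly = 0.0
    for cycle in range(1, settings.horizon_cycles + 1):
        df = discount_factor(cycle - 1, settings)
        start = occ[cycle - 1]
        basis = 0.5 * (start + occ[cycle]) if settings.half_cycle_correction else start
        state_costs = np.array(
            [
                state_cost_per_cycle(s, arm_name, cycle, costs, include_treatment=False)
                for s in HealthState
            ]
        )
        cycle_cost = float(basis @ state_costs)
        # Treatment cost: the cycle-1 induction course for the ECP arm is an
        # upfront course charged to the start-of-cycle cohort; all other
        # treatment costs accrue like recurring state costs.
        tx = treatment_cost(arm_name, cycle, costs)
        tx_basis = start[on] if (arm_name == ECP_ARM and cycle == 1) else basis[on]
        cycle_cost += tx_basis * tx
        cycle_cost += event_costs(trace.flows[cycle - 1], params, costs)
        total_cost += df * cycle_cost
        total_qaly += df * float(basis @ u) * settings.cycle_years
    return ArmOutcome(arm_name=arm_name, cost=total_cost, qaly=total_qaly)


def compare(
    intervention: ArmOutcome, comparator: ArmOutcome, settings: RunSettings
) -> EconResult:
    """Incremental comparison of intervention vs comparator."""
    dc = intervention.cost - comparator.cost
    dq = intervention.qaly - comparator.qaly
    icer: float | None = None
    if dq == 0.0:
        classification = "equal_effects"
    elif dc < 0.0 and dq > 0.0:
        classification = "dominant"
    elif dc > 0.0 and dq < 0.0:
        classification = "dominated"
    else:
        classification = "icer"
        icer = dc / dq
    nmb = settings.wtp_threshold * dq - dc
    return EconResult(
        intervention=intervention,
        comparator=comparator,
        delta_cost=dc,
        delta_qaly=dq,
        classification=classification,
        icer=icer,
        nmb_at_wtp=nmb,
        wtp_threshold=settings.wtp_threshold,
    )
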