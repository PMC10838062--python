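"""Deterministic Markov cohort engine for the four-state cGVHD model.

The state space follows the clinical course of steroid-refractory chronic
graft-vs-host disease on second-line therapy: patients start second-line
treatment, are assessed for response at the end of the first 12-week cycle
(the induction cycle), and thereafter face competing per-cycle risks of
treatment discontinuation (responders wean off while keeping their
response), disease progression, and death.  ``DEAD`` is absorbing; there is
no route back from ``PROGRESSED`` to either response state, nor from
off-treatment response back onto treatment.

The engine propagates state-occupancy fractions (a cohort model, not a
microsimulation); :func:`microsim_oracle` provides an independent
individual-level simulation of the same transition structure for
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "HealthState",
    "N_STATES",
    "ArmParameters",
    "RunSettings",
    "CohortTrace",
    "build_transition_row",
    "build_transition_matrix",
    "run_cohort",
    "microsim_oracle",
]


class HealthState(IntEnum):
    """Model health states, in the fixed order used by all arrays."""

    RESPONSE_ON_TREATMENT = 0
    RESPONSE_OFF_TREATMENT = 1
    PROGRESSED = 2
    DEAD = 3


N_STATES = len(HealthState)


@dataclass(frozen=True)
class ArmParameters:
    """Per-arm induction split and maintenance-phase transition probabilities.

    ``p_response_week12`` and ``p_progression_week12`` describe the
    response assessment at the end of the induction cycle and must be
    complementary.  The remaining probabilities apply per 12-week cycle
    from cycle 2 onward.  The same discontinuation and progression
    probabilities are shared between arms in the base case; mortality is
    state-specific (responder vs progressed), not arm-specific.
    """

    arm_name: str
    p_response_week12: float
    p_progression_week12: float
    p_progress_per_cycle: float
    p_death_responder_per_cycle: float
    p_death_progressed_per_cycle: float
    p_discontinue_per_cycle: float
    frac_death_respiratory: float = 0.0

    def validate(self) -> list[str]:
        errors: list[str] = []
        probs = {
            "p_response_week12": self.p_response_week12,
            "p_progression_week12": self.p_progression_week12,
            "p_progress_per_cycle": self.p_progress_per_cycle,
            "p_death_responder_per_cycle": self.p_death_responder_per_cycle,
            "p_death_progressed_per_cycle": self.p_death_progressed_per_cycle,
            "p_discontinue_per_cycle": self.p_discontinue_per_cycle,
            "frac_death_respiratory": self.frac_death_respiratory,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                errors.append(f"{self.arm_name}.{name}={p!r} outside [0, 1]")
        if abs(self.p_response_week12 + self.p_progression_week12 - 1.0) > 1e-9:
            errors.append(
                f"{self.arm_name}: p_response_week12 + p_progression_week12 = "
                f"{self.p_response_week12 + self.p_progression_week12!r}, expected 1"
            )
        out_response = (
            self.p_death_responder_per_cycle
            + self.p_progress_per_cycle
            + self.p_discontinue_per_cycle
        )
        if out_response > 1.0 + 1e-12:
            errors.append(
                f"{self.arm_name}: outgoing probabilities from "
                f"RESPONSE_ON_TREATMENT sum to {out_response!r} > 1"
            )
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class RunSettings:
    """Run configuration shared by both arms.

    ``half_cycle_correction`` selects the cycle-accounting convention used
    by the economics layer: recurring state costs and utilities accrue on
    the average of start- and end-of-cycle occupancy when enabled, and on
    start-of-cycle occupancy otherwise.  The induction cycle's one-off
    treatment-course cost is never half-cycle corrected (see economics).
    """

    horizon_cycles: int = 44
    cycle_length_weeks: float = 12.0
    annual_discount_rate: float = 0.05
    wtp_threshold: float = 50_000.0
    weeks_per_year: float = 52.0
    half_cycle_correction: bool = True

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_weeks / self.weeks_per_year

    def validate(self) -> list[str]:
        errors = []
        if not (isinstance(self.horizon_cycles, (int, np.integer)) and self.horizon_cycles >= 1):
            errors.append(f"horizon_cycles={self.horizon_cycles!r} must be a positive integer")
        if not 0.0 <= self.annual_discount_rate < 1.0:
            errors.append(
                f"annual_discount_rate={self.annual_discount_rate!r} outside [0, 1)"
            )
        if self.cycle_length_weeks <= 0:
            errors.append(f"cycle_length_weeks={self.cycle_length_weeks!r} must be > 0")
        if self.weeks_per_year <= 0:
            errors.append(f"weeks_per_year={self.weeks_per_year!r} must be > 0")
        if self.wtp_threshold < 0:
            errors.append(f"wtp_threshold={self.wtp_threshold!r} must be >= 0")
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class CohortTrace:
    """Cycle-indexed state occupancy and transition flows.

    ``occupancy[c, s]`` is the fraction of the cohort in state ``s`` at the
    start of cycle ``c + 1`` (row 0 is the initial distribution; row
    ``horizon`` the final one).  ``flows[c - 1, i, j]`` is the fraction of
    the cohort moving from state ``i`` to state ``j`` during cycle ``c``;
    the diagonal carries the remain-in-state mass.
    """

    occupancy: np.ndarray
    flows: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def entries_into(self, state: HealthState) -> np.ndarray:
        """Per-cycle inflow into ``state`` from other states (self-flow excluded)."""
        mask = np.ones(N_STATES, dtype=bool)
        mask[int(state)] = False
        return self.flows[:, mask, int(state)].sum(axis=1)

    def validate(self, atol: float = 1e-9) -> list[str]:
        errors = []
        occ, flows = self.occupancy, self.flows
        if occ.shape != (self.horizon + 1, N_STATES) or flows.shape != (
            self.horizon,
            N_STATES,
            N_STATES,
        ):
            return ["occupancy/flows shape mismatch"]
        if not np.allclose(occ.sum(axis=1), 1.0, atol=atol):
            errors.append("occupancy rows do not sum to 1")
        if np.any(occ < -atol):
            errors.append("negative occupancy")
        expected0 = np.zeros(N_STATES)
        expected0[HealthState.RESPONSE_ON_TREATMENT] = 1.0
        if not np.allclose(occ[0], expected0, atol=atol):
            errors.append("cohort does not start fully in RESPONSE_ON_TREATMENT")
        if not np.allclose(flows.sum(axis=(1, 2)), 1.0, atol=atol):
            errors.append("flow matrices do not conserve mass")
        if not np.allclose(occ[1:], flows.sum(axis=1), atol=atol):
            errors.append("occupancy inconsistent with flows")
        dead = occ[:, HealthState.DEAD]
        if np.any(np.diff(dead) < -atol):
            errors.append("DEAD occupancy decreases")
        return errors


def build_transition_row(
    state: HealthState, params: ArmParameters, cycle_index: int
) -> np.ndarray:
    """One row of the transition matrix for ``state`` during ``cycle_index``.

    Cycle 1 is the induction cycle: from ``RESPONSE_ON_TREATMENT`` the
    cohort splits into responders (stay) and progressors according to the
    week-12 assessment, with no death or discontinuation applied during
    induction.  From cycle 2 onward the competing per-cycle probabilities
    apply, with the residual mass remaining in state.  Off-treatment
    responders carry the same progression and mortality risks as
    on-treatment responders.
    """
    if cycle_index < 1:
        raise ValueError(f"cycle_index={cycle_index} must be >= 1")
    params.require_valid()
    row = np.zeros(N_STATES)
    s = HealthState(state)
    if s is HealthState.DEAD:
        row[HealthState.DEAD] = 1.0
        return row
    if s is HealthState.RESPONSE_ON_TREATMENT:
        if cycle_index == 1:
            row[HealthState.RESPONSE_ON_TREATMENT] = params.p_response_week12
            row[HealthState.PROGRESSED] = params.p_progression_week12
            return row
        row[HealthState.DEAD] = params.p_death_responder_per_cycle
        row[HealthState.PROGRESSED] = params.p_progress_per_cycle
        row[HealthState.RESPONSE_OFF_TREATMENT] = params.p_discontinue_per_cycle
        row[HealthState.RESPONSE_ON_TREATMENT] = 1.0 - row.sum()
    elif s is HealthState.RESPONSE_OFF_TREATMENT:
        row[HealthState.DEAD] = params.p_death_responder_per_cycle
        row[HealthState.PROGRESSED] = params.p_progress_per_cycle
        row[HealthState.RESPONSE_OFF_TREATMENT] = 1.0 - row.sum()
    elif s is HealthState.PROGRESSED:
        row[HealthState.DEAD] = params.p_death_progressed_per_cycle
        row[HealthState.PROGRESSED] = 1.0 - row.sum()
    if row[int(s)] < -1e-12:
        raise ValueError(
            f"outgoing probabilities from {s.name} sum to {1.0 - row[int(s)]:.6f} > 1"
        )
    row[int(s)] = max(row[int(s)], 0.0)
    return row


def build_transition_matrix(params: ArmParameters, cycle_index: int) -> np.ndarray:
    return np.vstack(
        [build_transition_row(s, params, cycle_index) for s in HealthState]
    )


def run_cohort(params: ArmParameters, settings: RunSettings) -> CohortTrace:
    """Propagate the cohort through ``settings.horizon_cycles`` cycles."""
    params.require_valid()
    settings.require_valid()
    horizon = settings.horizon_cycles
    occupancy = np.zeros((horizon + 1, N_STATES))
    occupancy[0, HealthState.RESPONSE_ON_TREATMENT] = 1.0
    flows = np.zeros((horizon, N_STATES, N_STATES))
    # The transition matrix only differs between cycle 1 and the rest.
    induction = build_transition_matrix(params, 1)
    maintenance = build_transition_matrix(params, 2)
    for cycle in range(1, horizon + 1):
        matrix = induction if cycle == 1 else maintenance
        flows[cycle - 1] = occupancy[cycle - 1][:, None] * matrix
        occupancy[cycle] = flows[cycle - 1].sum(axis=0)
    return CohortTrace(occupancy=occupancy, flows=flows)


def microsim_oracle(
    params: ArmParameters,
    settings: RunSettings,
    n_individuals: int,
    seed: int,
) -> CohortTrace:
    """Individual-level simulation of the same chain, for cross-validation.

    Simulates ``n_individuals`` independent patient paths under the exact
    per-cycle transition rows used by :func:`run_cohort` and returns
    empirical occupancy and flow fractions.  Agreement with the cohort
    trace within binomial Monte-Carlo error validates the deterministic
    engine; this function is intentionally a separate code path from the
    matrix propagation.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    params.require_valid()
    settings.require_valid()
    rng = np.random.default_rng(seed)
    horizon = settings.horizon_cycles
    states = np.full(n_individuals, int(HealthState.RESPONSE_ON_TREATMENT), dtype=np.int64)
    occupancy = np.zeros((horizon + 1, N_STATES))
    occupancy[0] = np.bincount(states, minlength=N_STATES) / n_individuals
    flows = np.zeros((horizon, N_STATES, N_STATES))
    induction = build_transition_matrix(params, 1)
    maintenance = build_transition_matrix(params, 2)
    for cycle in range(1, horizon + 1):
        matrix = induction if cycle == 1 else maintenance
        cum = np.cumsum(matrix, axis=1)
        u = rng.random(n_individuals)
        # Inverse-CDF draw of each individual's next state from its row.
        nxt = (u[:, None] > cum[states]).sum(axis=1)
        np.add.at(flows[cycle - 1], (states, nxt), 1.0)
        states = nxt
        occupancy[cycle] = np.bincount(states, minlength=N_STATES) / n_individuals
    flows /= n_individuals
    return CohortTrace(occupancy=occupancy, flows=flows)
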