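"""Derivation of per-cycle transition probabilities from summary evidence.

The published inputs are summary statistics — a week-12 response rate, a
relative risk of response between arms, cumulative mortality over a
median follow-up, a median treatment duration — while the Markov engine
needs per-cycle probabilities.  This module holds the closed-form
conversions:

* time-rescaling of a cumulative probability under a constant hazard,
  ``1 - (1 - p)**(t_to / t_from)``;
* the per-cycle event probability whose geometric survival curve has a
  given median, ``1 - 0.5**(cycle / median)``;
* the comparator's induction progression probability obtained by applying
  the relative risk of response to the intervention's response rate.

A proportional ("linear") rescaling alternative is provided for
transparency; only the constant-hazard form reproduces the published
per-cycle values from the quoted summary evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ArmParameters

__all__ = [
    "EvidenceInputs",
    "rescale_probability",
    "median_to_cycle_probability",
    "soc_progression_from_rr",
    "derive_arm_parameters",
]


@dataclass
class EvidenceInputs:
    """Summary clinical evidence from which per-cycle inputs are derived.

    ``responder_progression_cum`` is the cumulative progression risk for
    responders over ``progression_ref_weeks`` (annual in the base case);
    it is rescaled to the cycle length like the mortality probabilities.
    """

    ecp_response_week12: float = 0.802
    rr_response_ecp_vs_soc: float = 3.95
    responder_mortality_cum: float = 0.20
    nonresponder_mortality_cum: float = 0.53
    followup_weeks: float = 208.0
    median_treatment_weeks: float = 37.0
    responder_progression_cum: float = 0.041
    progression_ref_weeks: float = 52.0
    frac_death_respiratory: float = 0.55
    cycle_weeks: float = 12.0

    def validate(self) -> list[str]:
        errors = []
        for name in (
            "ecp_response_week12",
            "responder_mortality_cum",
            "nonresponder_mortality_cum",
            "responder_progression_cum",
        ):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                errors.append(f"evidence.{name}={p!r} outside (0, 1)")
        if not 0.0 <= self.frac_death_respiratory <= 1.0:
            errors.append(
                f"evidence.frac_death_respiratory={self.frac_death_respiratory!r} outside [0, 1]"
            )
        for name in (
            "followup_weeks",
            "median_treatment_weeks",
            "progression_ref_weeks",
            "cycle_weeks",
        ):
            d = getattr(self, name)
            if d <= 0:
                errors.append(f"evidence.{name}={d!r} must be > 0")
        if self.rr_response_ecp_vs_soc < self.ecp_response_week12:
            errors.append(
                "evidence.rr_response_ecp_vs_soc="
                f"{self.rr_response_ecp_vs_soc!r} < ecp_response_week12 "
                "(comparator response would exceed 1)"
            )
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("; ".join(errors))


def rescale_probability(
    p_cum: float,
    t_from: float,
    t_to: float,
    method: str = "constant_hazard",
) -> float:
    """Rescale a cumulative probability from one period to another.

    Under ``constant_hazard`` (the default, and the only form that
    reproduces the published per-cycle values), the event is assumed to
    follow an exponential time-to-event over ``t_from``:
    ``1 - (1 - p_cum) ** (t_to / t_from)``.  The ``linear`` alternative is
    simple proportional scaling ``p_cum * t_to / t_from`` (capped at 1).
    """
    if not 0.0 <= p_cum < 1.0:
        raise ValueError(f"p_cum={p_cum!r} must be in [0, 1); p_cum = 1 implies infinite hazard")
    if t_from <= 0 or t_to <= 0:
        raise ValueError("durations must be > 0")
    if method == "constant_hazard":
        return 1.0 - (1.0 - p_cum) ** (t_to / t_from)
    if method == "linear":
        return min(p_cum * t_to / t_from, 1.0)
    raise ValueError(f"unknown method {method!r}")


def median_to_cycle_probability(median_weeks: float, cycle_weeks: float) -> float:
    """Per-cycle event probability whose geometric survival has the given median."""
    if median_weeks <= 0 or cycle_weeks <= 0:
        raise ValueError("durations must be > 0")
    return 1.0 - 0.5 ** (cycle_weeks / median_weeks)


def soc_progression_from_rr(p_response_ecp: float, rr: float) -> float:
    """Comparator week-12 progression from the relative risk of response.

    The comparator's response probability is ``p_response_ecp / rr``; its
    progression probability is the complement.
    """
    if not 0.0 < p_response_ecp <= 1.0:
        raise ValueError(f"p_response_ecp={p_response_ecp!r} outside (0, 1]")
    if rr < p_response_ecp:
        raise ValueError(
            f"rr={rr!r} < p_response_ecp={p_response_ecp!r} would give response > 1"
        )
    return 1.0 - p_response_ecp / rr


def derive_arm_parameters(
    evidence: EvidenceInputs,
) -> tuple[ArmParameters, ArmParameters]:
    """Derive unrounded per-cycle parameters for both arms from the evidence.

    Both arms share the responder progression, mortality and
    discontinuation probabilities; only the induction response/progression
    split differs, with the comparator split obtained from the relative
    risk of response.
    """
    evidence.require_valid()
    cw = evidence.cycle_weeks
    shared = dict(
        p_progress_per_cycle=rescale_probability(
            evidence.responder_progression_cum, evidence.progression_ref_weeks, cw
        ),
        p_death_responder_per_cycle=rescale_probability(
            evidence.responder_mortality_cum, evidence.followup_weeks, cw
        ),
        p_death_progressed_per_cycle=rescale_probability(
            evidence.nonresponder_mortality_cum, evidence.followup_weeks, cw
        ),
        p_discontinue_per_cycle=median_to_cycle_probability(
            evidence.median_treatment_weeks, cw
        ),
        frac_death_respiratory=evidence.frac_death_respiratory,
    )
    p_resp = evidence.ecp_response_week12
    soc_prog = soc_progression_from_rr(p_resp, evidence.rr_response_ecp_vs_soc)
    ecp = ArmParameters(
        arm_name="ECP",
        p_response_week12=p_resp,
        p_progression_week12=1.0 - p_resp,
        **shared,
    )
    soc = ArmParameters(
        arm_name="SoC",
        p_response_week12=1.0 - soc_prog,
        p_progression_week12=soc_prog,
        **shared,
    )
    return ecp, soc
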