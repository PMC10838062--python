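"""Random, valid model specifications for property testing.

The generator targets the fixed four-state topology the costing rules
assume (response on/off treatment, progressed, dead) and draws every
numeric input at random while guaranteeing validity by construction:
per-cycle probabilities are drawn first, under a configurable cap on each
state's outgoing sum, and the evidence layer (cumulative probabilities,
median duration) is then obtained by inverting the derivation closed
forms, so the stated and derived parameter layers agree exactly and every
generated spec passes the same validation as a user-supplied file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .economics import CostInputs, SocComponent, UtilityInputs
from .model import RunSettings
from .spec import ModelSpec, PsaParameterSpec, StatedProbabilities
from .derivation import EvidenceInputs

__all__ = ["GeneratorConfig", "generate_model"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Bounds for the random model generator.

    ``max_outgoing`` caps the sum of competing per-cycle probabilities out
    of any state (< 1 so a remain-in-state residual always exists).
    """

    seed: int = 0
    n_models: int = 100
    max_outgoing: float = 0.6
    cost_scale: float = 50_000.0
    horizon_range: tuple[int, int] = (4, 30)

    def validate(self) -> list[str]:
        errors = []
        if not 0.0 < self.max_outgoing < 1.0:
            errors.append(f"max_outgoing={self.max_outgoing!r} outside (0, 1)")
        if self.cost_scale <= 0:
            errors.append(f"cost_scale={self.cost_scale!r} must be > 0")
        lo, hi = self.horizon_range
        if not 1 <= lo <= hi:
            errors.append(f"horizon_range={self.horizon_range!r} invalid")
        return errors


def _invert_rescale(p_cycle: float, t_from: float, t_to: float) -> float:
    """Cumulative probability over ``t_from`` whose rescaling to ``t_to`` is ``p_cycle``."""
    return 1.0 - (1.0 - p_cycle) ** (t_from / t_to)


def generate_model(config: GeneratorConfig, index: int) -> ModelSpec:
    """Deterministically generate the ``index``-th random valid spec."""
    errors = config.validate()
    if errors:
        raise ValueError("; ".join(errors))
    rng = np.random.default_rng([config.seed, index])
    cycle_weeks = 12.0

    # Per-cycle probabilities first, under the outgoing-sum cap; the
    # responder state carries three competing risks, progressed one.
    d_resp, progress, discontinue = (
        float(v) for v in rng.uniform(1e-4, config.max_outgoing / 3.0, size=3)
    )
    d_prog = float(rng.uniform(1e-4, config.max_outgoing))
    p_response = float(rng.uniform(0.05, 0.95))
    rr = float(1.0 / rng.uniform(0.1, 1.0))  # response ratio >= 1 keeps the comparator valid

    # Invert the derivation closed forms so evidence and stated layers agree.
    # The follow-up upper bound keeps inverted cumulative probabilities
    # strictly below 1 in double precision even at the outgoing-sum cap.
    followup_weeks = float(rng.uniform(52.0, 260.0))
    progression_ref_weeks = 52.0
    evidence = EvidenceInputs(
        ecp_response_week12=p_response,
        rr_response_ecp_vs_soc=rr,
        responder_mortality_cum=_invert_rescale(d_resp, followup_weeks, cycle_weeks),
        nonresponder_mortality_cum=_invert_rescale(d_prog, followup_weeks, cycle_weeks),
        followup_weeks=followup_weeks,
        median_treatment_weeks=float(cycle_weeks * np.log(0.5) / np.log1p(-discontinue)),
        responder_progression_cum=_invert_rescale(
            progress, progression_ref_weeks, cycle_weeks
        ),
        progression_ref_weeks=progression_ref_weeks,
        frac_death_respiratory=float(rng.uniform(0.0, 1.0)),
        cycle_weeks=cycle_weeks,
    )
    probabilities = StatedProbabilities(
        progression_responders_annual=evidence.responder_progression_cum,
        progression_ref_weeks=progression_ref_weeks,
        p_death_responder_per_cycle=d_resp,
        p_death_progressed_per_cycle=d_prog,
        p_discontinue_per_cycle=discontinue,
        frac_death_respiratory=evidence.frac_death_respiratory,
    )

    weights = rng.dirichlet(np.ones(3))
    cost = lambda: float(rng.uniform(0.0, config.cost_scale))  # noqa: E731
    costs = CostInputs(
        ecp_cycle1=cost(),
        ecp_maintenance=cost(),
        soc_components=[
            SocComponent("component_a", cost(), float(weights[0])),
            SocComponent("component_b", cost(), float(weights[1])),
            SocComponent("component_c", cost(), float(weights[2])),
        ],
        prednisone_start=cost(),
        prednisone_down=cost(),
        subsequent_therapy=cost(),
        progression_event=cost(),
        infection_hospitalization=cost(),
        death_respiratory_event=cost(),
        management_response=cost(),
        management_progressed=cost(),
    )

    u_progressed, u_response = np.sort(rng.uniform(0.0, 1.0, size=2))
    utilities = UtilityInputs(
        u_response=float(u_response), u_progressed=float(u_progressed), u_dead=0.0
    )

    settings = RunSettings(
        horizon_cycles=int(rng.integers(config.horizon_range[0], config.horizon_range[1] + 1)),
        cycle_length_weeks=cycle_weeks,
        annual_discount_rate=float(rng.uniform(0.0, 0.1)),
        wtp_threshold=50_000.0,
        weeks_per_year=52.0,
        half_cycle_correction=bool(rng.integers(0, 2)),
    )

    psa = [
        PsaParameterSpec(path="evidence.ecp_response_week12", family="beta"),
        PsaParameterSpec(path="probabilities.p_death_responder_per_cycle", family="beta"),
        PsaParameterSpec(path="costs.subsequent_therapy", family="lognormal"),
    ]
    spec = ModelSpec(
        evidence=evidence,
        probabilities=probabilities,
        costs=costs,
        utilities=utilities,
        settings=settings,
        psa=psa,
        metadata={"label": f"synthetic model {config.seed}/{index}", "synthetic": True},
    )
    return spec
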