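"""Declarative model specification: loading, validation, serialization.

A model spec is a single YAML document carrying every input of one
intervention-vs-comparator comparison: the upstream summary evidence, the
published per-cycle transition probabilities, costs, utilities, run
settings and the probabilistic-sensitivity-analysis (PSA) parameter list.
The packaged ``data/base_case.yaml`` transcribes the published input table
for photopheresis vs weighted standard-of-care and is itself under test.

Two parameter layers coexist deliberately:

* ``evidence`` holds the summary statistics (cumulative mortality over
  follow-up, median treatment duration, relative risk of response) from
  which the per-cycle values can be derived with
  :mod:`gvhdcea.derivation`;
* ``probabilities`` holds the per-cycle values as published, which
  parameterize the chain.  The ``derive`` report compares the two layers
  so every published input is reproduced rather than trusted.
"""

from __future__ import annotations

import copy
import hashlib
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .derivation import (
    EvidenceInputs,
    derive_arm_parameters,
    rescale_probability,
    soc_progression_from_rr,
)
from .economics import (
    ArmOutcome,
    CostInputs,
    EconResult,
    SocComponent,
    UtilityInputs,
    accrue,
    compare,
)
from .model import ArmParameters, CohortTrace, HealthState, RunSettings, run_cohort

__all__ = [
    "StatedProbabilities",
    "PsaParameterSpec",
    "ModelSpec",
    "SpecValidationError",
    "load_spec",
    "loads",
    "dump_spec",
    "dumps",
    "base_case_spec",
    "run_base_case",
]

logger = logging.getLogger("gvhdcea")

PSA_FAMILIES = ("beta", "lognormal", "fixed")


class SpecValidationError(ValueError):
    """Raised when a spec file violates one or more invariants."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid model spec:\n  - " + "\n  - ".join(self.errors))


@dataclass
class StatedProbabilities:
    """Per-cycle transition probabilities as published.

    ``progression_responders_annual`` is the responders' progression risk
    over ``progression_ref_weeks`` (a year); the engine rescales it to the
    cycle length under a constant hazard.
    """

    progression_responders_annual: float = 0.041
    progression_ref_weeks: float = 52.0
    p_death_responder_per_cycle: float = 0.013
    p_death_progressed_per_cycle: float = 0.042
    p_discontinue_per_cycle: float = 0.201
    frac_death_respiratory: float = 0.55

    def validate(self) -> list[str]:
        errors = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "progression_ref_weeks":
                if v <= 0:
                    errors.append(f"probabilities.{f.name}={v!r} must be > 0")
            elif not 0.0 <= v <= 1.0:
                errors.append(f"probabilities.{f.name}={v!r} outside [0, 1]")
        return errors


@dataclass
class PsaParameterSpec:
    """One PSA-varied (or explicitly fixed) parameter.

    ``path`` is a dotted reference into the model spec
    (e.g. ``probabilities.p_death_responder_per_cycle`` or
    ``costs.soc_components.tacrolimus``).  ``spread_abs`` is an absolute
    standard error; ``spread_frac`` a fraction of the base value (default
    0.2 when neither is given).  ``lower``/``upper`` optionally truncate
    draws (used to keep utility draws on the [0, 1] scale).
    """

    path: str
    family: str
    spread_frac: float | None = None
    spread_abs: float | None = None
    lower: float | None = None
    upper: float | None = None

    def spread_for(self, mean: float) -> float:
        if self.spread_abs is not None:
            return self.spread_abs
        frac = 0.2 if self.spread_frac is None else self.spread_frac
        return abs(mean) * frac

    def validate(self) -> list[str]:
        errors = []
        if self.family not in PSA_FAMILIES:
            errors.append(
                f"psa[{self.path}].family={self.family!r} not one of {PSA_FAMILIES}"
            )
        if self.spread_frac is not None and self.spread_frac < 0:
            errors.append(f"psa[{self.path}].spread_frac={self.spread_frac!r} negative")
        if self.spread_abs is not None and self.spread_abs < 0:
            errors.append(f"psa[{self.path}].spread_abs={self.spread_abs!r} negative")
        return errors


@dataclass
class ModelSpec:
    """Full parameterization of one comparison."""

    evidence: EvidenceInputs = field(default_factory=EvidenceInputs)
    probabilities: StatedProbabilities = field(default_factory=StatedProbabilities)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    settings: RunSettings = field(default_factory=RunSettings)
    psa: list[PsaParameterSpec] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- derived parameters -------------------------------------------------

    def arm_parameters(self) -> tuple[ArmParameters, ArmParameters]:
        """Engine inputs: induction splits from the evidence layer, per-cycle
        probabilities from the published table (progression rescaled from
        its annual reference period)."""
        p_resp = self.evidence.ecp_response_week12
        soc_prog = soc_progression_from_rr(p_resp, self.evidence.rr_response_ecp_vs_soc)
        tp = self.probabilities
        shared = dict(
            p_progress_per_cycle=rescale_probability(
                tp.progression_responders_annual,
                tp.progression_ref_weeks,
                self.settings.cycle_length_weeks,
            ),
            p_death_responder_per_cycle=tp.p_death_responder_per_cycle,
            p_death_progressed_per_cycle=tp.p_death_progressed_per_cycle,
            p_discontinue_per_cycle=tp.p_discontinue_per_cycle,
            frac_death_respiratory=tp.frac_death_respiratory,
        )
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

    # -- validation ---------------------------------------------------------

    def validate(self, utility_ordering: bool = True) -> list[str]:
        errors: list[str] = []
        errors += self.evidence.validate()
        errors += self.probabilities.validate()
        errors += self.costs.validate()
        errors += self.utilities.validate(ordering=utility_ordering)
        errors += self.settings.validate()
        for p in self.psa:
            errors += p.validate()
        if abs(self.evidence.cycle_weeks - self.settings.cycle_length_weeks) > 1e-9:
            errors.append(
                f"evidence.cycle_weeks={self.evidence.cycle_weeks!r} != "
                f"settings.cycle_length_weeks={self.settings.cycle_length_weeks!r}"
            )
        if not errors:
            for arm in self.arm_parameters():
                errors += arm.validate()
            for p in self.psa:
                try:
                    base = self.get_value(p.path)
                except KeyError as exc:
                    errors.append(str(exc.args[0]))
                    continue
                if p.family == "beta" and not 0.0 <= base <= 1.0:
                    errors.append(
                        f"psa[{p.path}]: beta family requires a base value in [0, 1], got {base!r}"
                    )
                if p.family == "lognormal" and base < 0.0:
                    # base 0 degenerates to a point mass (zero spread), which
                    # sampling handles; negative bases are meaningless.
                    errors.append(
                        f"psa[{p.path}]: lognormal family requires a non-negative base value, got {base!r}"
                    )
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise SpecValidationError(errors)

    # -- dotted-path access (used by DSA, PSA, scenarios) --------------------

    def get_value(self, path: str) -> float:
        obj, attr = self._resolve(path)
        return getattr(obj, attr)

    def with_value(self, path: str, value: float) -> "ModelSpec":
        """A deep copy of the spec with one field replaced."""
        out = copy.deepcopy(self)
        obj, attr = out._resolve(path)
        setattr(obj, attr, value)
        return out

    def with_values(self, overrides: dict[str, float]) -> "ModelSpec":
        out = copy.deepcopy(self)
        for path, value in overrides.items():
            obj, attr = out._resolve(path)
            setattr(obj, attr, value)
        return out

    def _resolve(self, path: str):
        parts = path.split(".")
        obj = self
        for i, part in enumerate(parts[:-1]):
            if part == "soc_components":
                label = parts[i + 1]
                for comp in obj.soc_components:
                    if comp.label == label:
                        return comp, "cost"
                raise KeyError(f"unknown SoC component {label!r} in path {path!r}")
            if not hasattr(obj, part):
                raise KeyError(f"unknown path segment {part!r} in {path!r}")
            obj = getattr(obj, part)
        attr = parts[-1]
        if not hasattr(obj, attr):
            raise KeyError(f"unknown field {attr!r} in path {path!r}")
        value = getattr(obj, attr)
        if not isinstance(value, (int, float)):
            raise KeyError(f"path {path!r} does not address a numeric field")
        return obj, attr

    # -- evaluation ---------------------------------------------------------

    def traces(self) -> dict[str, CohortTrace]:
        ecp, soc = self.arm_parameters()
        return {
            ecp.arm_name: run_cohort(ecp, self.settings),
            soc.arm_name: run_cohort(soc, self.settings),
        }

    def evaluate(self) -> EconResult:
        """Run both arms and return the incremental cost-utility result."""
        ecp, soc = self.arm_parameters()
        outcomes = []
        for params in (ecp, soc):
            trace = run_cohort(params, self.settings)
            outcomes.append(
                accrue(trace, self.costs, self.utilities, self.settings, params.arm_name, params)
            )
        return compare(outcomes[0], outcomes[1], self.settings)

    def derivation_report(self) -> pd.DataFrame:
        """Published per-cycle values vs their derivation from the evidence."""
        ecp_d, soc_d = derive_arm_parameters(self.evidence)
        _, soc_s = self.arm_parameters()
        tp = self.probabilities
        rows = [
            ("soc_progression_week12", soc_s.p_progression_week12, soc_d.p_progression_week12),
            (
                "p_progress_per_cycle",
                rescale_probability(
                    tp.progression_responders_annual,
                    tp.progression_ref_weeks,
                    self.settings.cycle_length_weeks,
                ),
                ecp_d.p_progress_per_cycle,
            ),
            ("p_death_responder_per_cycle", tp.p_death_responder_per_cycle, ecp_d.p_death_responder_per_cycle),
            ("p_death_progressed_per_cycle", tp.p_death_progressed_per_cycle, ecp_d.p_death_progressed_per_cycle),
            ("p_discontinue_per_cycle", tp.p_discontinue_per_cycle, ecp_d.p_discontinue_per_cycle),
        ]
        df = pd.DataFrame(rows, columns=["parameter", "stated", "derived"])
        df["difference"] = df["derived"] - df["stated"]
        return df

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "metadata": dict(self.metadata),
            "evidence": asdict(self.evidence),
            "probabilities": asdict(self.probabilities),
            "costs": asdict(self.costs),
            "utilities": asdict(self.utilities),
            "settings": asdict(self.settings),
            "psa": [
                {k: v for k, v in asdict(p).items() if v is not None} for p in self.psa
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        errors: list[str] = []
        known_sections = {
            "metadata",
            "evidence",
            "probabilities",
            "costs",
            "utilities",
            "settings",
            "psa",
        }
        unknown = set(data) - known_sections
        if unknown:
            errors.append(f"unknown top-level sections: {sorted(unknown)}")

        def build(klass, section: str):
            payload = dict(data.get(section) or {})
            names = {f.name for f in fields(klass)}
            extra = set(payload) - names
            if extra:
                errors.append(f"{section}: unknown fields {sorted(extra)}")
                for k in extra:
                    payload.pop(k)
            try:
                return klass(**payload)
            except TypeError as exc:
                errors.append(f"{section}: {exc}")
                return klass()

        evidence = build(EvidenceInputs, "evidence")
        probabilities = build(StatedProbabilities, "probabilities")
        costs_payload = dict(data.get("costs") or {})
        components_payload = costs_payload.pop("soc_components", None)
        cost_names = {f.name for f in fields(CostInputs)}
        extra = set(costs_payload) - cost_names
        if extra:
            errors.append(f"costs: unknown fields {sorted(extra)}")
            for k in extra:
                costs_payload.pop(k)
        costs = CostInputs(**costs_payload)
        if components_payload is not None:
            try:
                costs.soc_components = [SocComponent(**c) for c in components_payload]
            except TypeError as exc:
                errors.append(f"costs.soc_components: {exc}")
        utilities = build(UtilityInputs, "utilities")
        settings = build(RunSettings, "settings")
        psa = []
        for i, entry in enumerate(data.get("psa") or []):
            try:
                psa.append(PsaParameterSpec(**entry))
            except TypeError as exc:
                errors.append(f"psa[{i}]: {exc}")
        if errors:
            raise SpecValidationError(errors)
        return cls(
            evidence=evidence,
            probabilities=probabilities,
            costs=costs,
            utilities=utilities,
            settings=settings,
            psa=psa,
            metadata=dict(data.get("metadata") or {}),
        )


def loads(text: str) -> ModelSpec:
    """Parse and fully validate a spec document from YAML text."""
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SpecValidationError([f"YAML parse error: {exc}"]) from exc
    if not isinstance(data, dict):
        raise SpecValidationError(["spec document must be a mapping"])
    spec = ModelSpec.from_dict(data)
    spec.require_valid()
    return spec


def load_spec(path: str | Path) -> ModelSpec:
    return loads(Path(path).read_text())


def dumps(spec: ModelSpec) -> str:
    return yaml.safe_dump(spec.to_dict(), sort_keys=True, default_flow_style=False)


def dump_spec(spec: ModelSpec, path: str | Path) -> None:
    Path(path).write_text(dumps(spec))


def spec_digest(spec: ModelSpec) -> str:
    return hashlib.sha256(dumps(spec).encode()).hexdigest()[:16]


def base_case_spec() -> ModelSpec:
    """The packaged base-case spec (the published input table)."""
    from importlib.resources import files

    text = files("gvhdcea").joinpath("data/base_case.yaml").read_text()
    return loads(text)


def _trace_frame(trace: CohortTrace) -> pd.DataFrame:
    occ = pd.DataFrame(
        trace.occupancy, columns=[s.name.lower() for s in HealthState]
    )
    occ.index.name = "cycle"
    entries = trace.entries_into(HealthState.PROGRESSED)
    deaths_prog = trace.flows[:, int(HealthState.PROGRESSED), int(HealthState.DEAD)]
    occ["entries_into_progressed"] = [0.0, *entries]
    occ["deaths_from_progressed"] = [0.0, *deaths_prog]
    return occ


def _summary_frame(result: EconResult) -> pd.DataFrame:
    rows = []
    for outcome, dc, dq in (
        (result.intervention, result.delta_cost, result.delta_qaly),
        (result.comparator, None, None),
    ):
        rows.append(
            {
                "arm": outcome.arm_name,
                "cost": outcome.cost,
                "qaly": outcome.qaly,
                "delta_cost": dc,
                "delta_qaly": dq,
                "classification": result.classification if dc is not None else None,
                "icer": result.icer if dc is not None else None,
                "nmb_at_wtp": result.nmb_at_wtp if dc is not None else None,
            }
        )
    return pd.DataFrame(rows)


def run_base_case(spec: ModelSpec, out_dir: str | Path) -> dict[str, Path]:
    """Run the deterministic pipeline and write all report tables.

    Writes one occupancy/flow trace per arm, the two-row cost-utility
    summary, and the stated-vs-derived parameter report.  Returns the
    mapping of report names to file paths.
    """
    spec.require_valid()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "running base case: spec digest %s, horizon %d cycles, discount %.3f",
        spec_digest(spec),
        spec.settings.horizon_cycles,
        spec.settings.annual_discount_rate,
    )
    paths: dict[str, Path] = {}
    for arm_name, trace in spec.traces().items():
        p = out / f"trace_{arm_name.lower()}.csv"
        _trace_frame(trace).to_csv(p, float_format="%.10g")
        paths[f"trace_{arm_name.lower()}"] = p
    result = spec.evaluate()
    p = out / "summary.csv"
    _summary_frame(result).to_csv(p, index=False, float_format="%.10g")
    paths["summary"] = p
    p = out / "derivation.csv"
    spec.derivation_report().to_csv(p, index=False, float_format="%.10g")
    paths["derivation"] = p
    logger.info(
        "base case: %s cost %.0f QALY %.3f | %s cost %.0f QALY %.3f | %s",
        result.intervention.arm_name,
        result.intervention.cost,
        result.intervention.qaly,
        result.comparator.arm_name,
        result.comparator.cost,
        result.comparator.qaly,
        result.classification,
    )
    return paths
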