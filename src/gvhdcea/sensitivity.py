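"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-runs the full pipeline with a single
parameter replaced at its low and high value; dependent quantities (the
comparator's induction split, the per-cycle progression probability, the
weighted comparator drug cost) are re-derived on every run because the
pipeline always evaluates from the spec.

The PSA draws each varied parameter independently from its assigned
family — beta for probabilities (method-of-moments fit to the base value
and standard error), lognormal for positive quantities (moment-matched on
the natural scale) — and records the incremental cost/QALY pair per
iteration.  No correlation structure is imposed.  Iteration ``i`` of a run
seeded with ``s`` uses the dedicated substream ``default_rng([s, i])`` so
results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import EconResult
from .spec import ModelSpec, PsaParameterSpec

__all__ = [
    "PsaResult",
    "DEFAULT_WTP_GRID",
    "one_way_dsa",
    "tornado",
    "beta_from_moments",
    "lognormal_from_moments",
    "sample_parameters",
    "run_psa",
    "scenario",
]

DEFAULT_WTP_GRID = tuple(float(w) for w in range(0, 100_001, 5_000))


@dataclass
class PsaResult:
    """Per-iteration incremental outcomes and their summaries.

    ``iterations`` has one (delta_cost, delta_qaly) row per iteration.
    ``icer_percentiles`` are the 2.5th/97.5th percentiles of the raw
    per-iteration ratio, computed over iterations with ``|delta_qaly|``
    above the configured floor; ``n_icer_excluded`` counts the rest.
    """

    iterations: np.ndarray
    ceac: dict[float, float]
    icer_percentiles: tuple[float, float]
    prob_ce_at_wtp: float
    wtp_threshold: float
    n_icer_excluded: int = 0
    seed: int | None = None

    @property
    def n_iterations(self) -> int:
        return self.iterations.shape[0]

    def nmb(self, wtp: float) -> np.ndarray:
        return wtp * self.iterations[:, 1] - self.iterations[:, 0]

    def scatter_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.iterations, columns=["delta_cost", "delta_qaly"])
        df.index.name = "iteration"
        df["nmb"] = self.nmb(self.wtp_threshold)
        return df

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.ceac.items()), columns=["wtp", "prob_cost_effective"]
        )


# -- deterministic sensitivity ----------------------------------------------


def one_way_dsa(
    spec: ModelSpec, path: str, low: float, high: float
) -> tuple[EconResult, EconResult]:
    """Re-run the base case with one parameter at its low and high value."""
    if low > high:
        raise ValueError(f"low={low!r} > high={high!r} for {path!r}")
    results = []
    for value in (low, high):
        replaced = spec.with_value(path, value)
        errors = replaced.validate(utility_ordering=False)
        if errors:
            raise ValueError(
                f"DSA value {value!r} for {path!r} violates: " + "; ".join(errors)
            )
        results.append(replaced.evaluate())
    return results[0], results[1]


def tornado(
    spec: ModelSpec,
    ranges: list[tuple[str, float, float]] | None = None,
    rel_range: float = 0.2,
) -> pd.DataFrame:
    """One-way results for every parameter, widest net-benefit swing first.

    ``ranges`` is a list of (path, low, high); when omitted, every
    non-fixed PSA parameter is varied by ``rel_range`` of its base value.
    """
    if ranges is None:
        ranges = []
        for p in varied_parameters(spec):
            base = spec.get_value(p.path)
            ranges.append((p.path, base * (1 - rel_range), base * (1 + rel_range)))
    rows = []
    for path, low, high in ranges:
        res_low, res_high = one_way_dsa(spec, path, low, high)
        rows.append(
            {
                "parameter": path,
                "low": low,
                "high": high,
                "nmb_low": res_low.nmb_at_wtp,
                "nmb_high": res_high.nmb_at_wtp,
                "width": abs(res_high.nmb_at_wtp - res_low.nmb_at_wtp),
                "classification_low": res_low.classification,
                "classification_high": res_high.classification,
            }
        )
    df = pd.DataFrame(rows).sort_values("width", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def varied_parameters(spec: ModelSpec) -> list[PsaParameterSpec]:
    return [p for p in spec.psa if p.family != "fixed"]


# -- probabilistic sensitivity ----------------------------------------------


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta(alpha, beta) matching the given mean and standard deviation."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean {mean!r} outside (0, 1)")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"spread {sd!r} too large for a beta distribution with mean {mean!r}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log for a lognormal with the given natural-scale moments."""
    if mean <= 0.0:
        raise ValueError(f"lognormal mean {mean!r} must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def sample_parameters(
    psa_specs: list[PsaParameterSpec],
    base_values: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, float]:
    """One independent draw of every parameter, keyed by path.

    Fixed parameters and zero spreads return the base value unchanged.
    Draws are truncated to any declared (lower, upper) bounds by clipping.
    """
    draw: dict[str, float] = {}
    for p in psa_specs:
        mean = base_values[p.path]
        if p.family == "fixed":
            draw[p.path] = mean
            continue
        sd = p.spread_for(mean)
        if sd == 0.0:
            draw[p.path] = mean
            continue
        if p.family == "beta":
            try:
                a, b = beta_from_moments(mean, sd)
            except ValueError as exc:
                raise ValueError(f"psa[{p.path}]: {exc}") from exc
            value = float(rng.beta(a, b))
        elif p.family == "lognormal":
            mu, sigma = lognormal_from_moments(mean, sd)
            value = float(rng.lognormal(mu, sigma))
        else:
            raise ValueError(f"psa[{p.path}]: unknown family {p.family!r}")
        if p.lower is not None:
            value = max(value, p.lower)
        if p.upper is not None:
            value = min(value, p.upper)
        draw[p.path] = value
    return draw


def run_psa(
    spec: ModelSpec,
    n_iterations: int = 1000,
    seed: int = 0,
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID,
    dq_floor: float = 1e-6,
) -> PsaResult:
    """Monte-Carlo re-evaluation of the model under parameter uncertainty."""
    if n_iterations < 2:
        raise ValueError("n_iterations must be >= 2")
    wtp = spec.settings.wtp_threshold
    if wtp not in wtp_grid:
        wtp_grid = tuple(sorted({*wtp_grid, wtp}))
    base_values = {p.path: spec.get_value(p.path) for p in spec.psa}
    iterations = np.empty((n_iterations, 2))
    for i in range(n_iterations):
        rng = np.random.default_rng([seed, i])
        draw = sample_parameters(spec.psa, base_values, rng)
        result = spec.with_values(draw).evaluate()
        iterations[i] = (result.delta_cost, result.delta_qaly)
    dc, dq = iterations[:, 0], iterations[:, 1]
    ceac = {
        float(w): float(np.mean(w * dq - dc > 0.0)) for w in wtp_grid
    }
    keep = np.abs(dq) >= dq_floor
    ratios = dc[keep] / dq[keep]
    if ratios.size:
        lo, hi = np.percentile(ratios, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return PsaResult(
        iterations=iterations,
        ceac=ceac,
        icer_percentiles=(float(lo), float(hi)),
        prob_ce_at_wtp=ceac[float(wtp)],
        wtp_threshold=wtp,
        n_icer_excluded=int((~keep).sum()),
        seed=seed,
    )


# -- scenario re-runs --------------------------------------------------------


def scenario(spec: ModelSpec, overrides: dict[str, float]) -> EconResult:
    """Evaluate the model with a named set of field overrides.

    Typical uses: a shortened time horizon
    (``{"settings.horizon_cycles": 22}``) or a re-costed subsequent-therapy
    blend (``{"costs.subsequent_therapy": ...}``).
    """
    replaced = spec.with_values(overrides)
    errors = replaced.validate(utility_ordering=False)
    if errors:
        raise ValueError("scenario overrides violate: " + "; ".join(errors))
    return replaced.evaluate()
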