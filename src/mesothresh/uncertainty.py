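"""Monte Carlo propagation of parameter uncertainty.

Each sampled parameter is drawn independently from a normal distribution
centred on its mean with standard deviation ``cv * mean`` (default CV 20%),
truncated to the parameter's published range where one exists and to its
natural domain otherwise (non-negative, and at most 1 for proportions).  An
alternative ``"assumed_range"`` policy additionally truncates range-less
parameters to a +/-20% band around the mean.  Temporal parameters
(durations, ages) are held fixed.

Per draw the closed-form thresholds are evaluated, and the output
distributions are summarised by their medians and central 68%/95% credible
intervals.  Draws whose critical-rats numerator is non-positive describe a
population that declines even without rats; no finite rat threshold exists
there, so such draws are excluded from the critical-rats/critical-cats
summaries and from the band lines, and their count is reported.  Threshold
lines evaluated on a grid of cat abundances give the quantile bands that
partition cat-rat phase space into decline/increase risk regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import ParameterSpec
from .thresholds import PredatorScenario, thresholds_from_values

__all__ = [
    "SamplingPlan",
    "OutputSummary",
    "UncertaintyReport",
    "REGION_LABELS",
    "sample_parameters",
    "evaluate_draws",
    "monte_carlo_summary",
    "phase_space_bands",
    "classify_scenario",
]

#: phase-space region labels, ordered from most to least tropicbird risk
REGION_LABELS = (
    "decline >97.5%",
    "decline 84-97.5%",
    "decline 50-84%",
    "increase 50-84%",
    "increase 84-97.5%",
    "increase >97.5%",
)

_BAND_COLUMNS = ("n_cats", "q2p5", "q16", "q50", "q84", "q97p5")

#: assumed half-width of the truncation band, as a fraction of the mean,
#: for parameters published without a range
ASSUMED_RANGE_FRACTION = 0.20


@dataclass(frozen=True)
class SamplingPlan:
    """Settings for one Monte Carlo run.

    ``truncation`` is ``"natural"`` (default: natural domain only where no
    range is published) or ``"assumed_range"`` (additionally +/-20% of the
    mean).  Per-parameter ``overrides`` map a name to any of ``cv``, ``sd``,
    ``low``, ``high``.
    """

    n_draws: int = 100_000
    seed: int | None = None
    cv_default: float | None = None
    truncation: str = "natural"
    overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError(f"n_draws must be >= 1, got {self.n_draws}")
        if self.truncation not in ("assumed_range", "natural"):
            raise ValueError(f"unknown truncation policy {self.truncation!r}")
        if self.cv_default is not None and self.cv_default < 0:
            raise ValueError(f"cv_default must be >= 0, got {self.cv_default}")


@dataclass(frozen=True)
class OutputSummary:
    """Median and central credible intervals of one model output."""

    median: float
    ci68: tuple[float, float]
    ci95: tuple[float, float]
    n_draws: int
    n_invalid: int = 0


@dataclass(frozen=True)
class UncertaintyReport:
    """Monte Carlo summaries per output, plus an optional phase-space band
    table over a cat-abundance grid."""

    outputs: dict[str, OutputSummary]
    n_draws: int
    seed: int | None
    n_invalid: int = 0
    band_table: pd.DataFrame | None = None


def _bounds(spec: ParameterSpec, plan: SamplingPlan, ov: Mapping) -> tuple[float, float]:
    if "low" in ov or "high" in ov:
        lo = float(ov.get("low", spec.natural_low))
        hi = float(ov.get("high", spec.natural_high))
    elif spec.range_low is not None:
        lo, hi = spec.range_low, spec.range_high
    elif plan.truncation == "assumed_range":
        half = ASSUMED_RANGE_FRACTION * abs(spec.mean)
        lo = max(spec.natural_low, spec.mean - half)
        hi = min(spec.natural_high, spec.mean + half)
    else:
        lo, hi = spec.natural_low, spec.natural_high
    if not lo < hi:
        raise ValueError(f"{spec.name}: unsatisfiable truncation [{lo}, {hi}]")
    return lo, hi


def sample_parameters(
    specs: Iterable[ParameterSpec],
    plan: SamplingPlan,
) -> pd.DataFrame:
    """Draw ``plan.n_draws`` independent parameter sets.

    Returns a DataFrame with one column per parameter (unsampled parameters
    appear as constant columns).  Identical plans produce bit-identical
    draws.
    """
    rng = np.random.default_rng(plan.seed)
    n = plan.n_draws
    cols: dict[str, np.ndarray] = {}
    for spec in specs:
        ov = plan.overrides.get(spec.name, {})
        cv = float(ov["cv"]) if "cv" in ov else (
            plan.cv_default if plan.cv_default is not None else spec.cv
        )
        sd = float(ov["sd"]) if "sd" in ov else cv * abs(spec.mean)
        if not spec.sampled or sd == 0.0:
            cols[spec.name] = np.full(n, spec.mean)
            continue
        lo, hi = _bounds(spec, plan, ov)
        a, b = (lo - spec.mean) / sd, (hi - spec.mean) / sd
        cols[spec.name] = stats.truncnorm.rvs(
            a, b, loc=spec.mean, scale=sd, size=n, random_state=rng
        )
    return pd.DataFrame(cols)


def evaluate_draws(
    draws: pd.DataFrame, eta_target: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Closed-form thresholds per draw.

    Returns ``(outputs, valid, viable)``: ``outputs`` has columns
    ``critical_rats``, ``cat_equivalence`` and ``critical_cats``; ``valid``
    flags draws whose rat-predation denominator is positive (the closed
    forms are undefined otherwise); ``viable`` additionally requires a
    positive critical-rats numerator, i.e. a finite rat threshold exists.
    """
    values = {k: draws[k].to_numpy() for k in draws.columns}
    cr, ce, cc, valid = thresholds_from_values(values, eta_target)
    out = pd.DataFrame(
        {"critical_rats": cr, "cat_equivalence": ce, "critical_cats": cc}
    )
    return out, valid, valid & (np.asarray(cr) > 0.0)


def _summary(x: np.ndarray, n_draws: int, n_invalid: int) -> OutputSummary:
    q = np.percentile(x, [2.5, 16.0, 50.0, 84.0, 97.5])
    return OutputSummary(
        median=float(q[2]),
        ci68=(float(q[1]), float(q[3])),
        ci95=(float(q[0]), float(q[4])),
        n_draws=n_draws,
        n_invalid=n_invalid,
    )


def monte_carlo_summary(
    specs: Iterable[ParameterSpec],
    plan: SamplingPlan,
    eta_target: float = 1.0,
) -> UncertaintyReport:
    """Medians and 68%/95% central credible intervals of the threshold
    outputs under the sampling plan.

    Cat equivalence is summarised over every draw with positive rat
    predation; the critical abundances additionally condition on draws
    where a finite threshold exists (positive numerator).  Excluded draws
    are counted in ``n_invalid`` per output.
    """
    draws = sample_parameters(specs, plan)
    out, valid, viable = evaluate_draws(draws, eta_target)
    if not valid.any() or not viable.any():
        raise RuntimeError("every Monte Carlo draw violated model preconditions")
    masks = {
        "critical_rats": viable,
        "cat_equivalence": valid,
        "critical_cats": viable,
    }
    outputs = {
        name: _summary(
            out[name].to_numpy()[mask], plan.n_draws, int((~mask).sum())
        )
        for name, mask in masks.items()
    }
    return UncertaintyReport(
        outputs=outputs,
        n_draws=plan.n_draws,
        seed=plan.seed,
        n_invalid=int((~viable).sum()),
    )


def phase_space_bands(
    specs: Iterable[ParameterSpec],
    plan: SamplingPlan,
    cat_grid: Sequence[float],
    eta_target: float = 1.0,
) -> pd.DataFrame:
    """Quantile bands of the threshold line over a cat-abundance grid.

    For each draw the line ``max(0, critical_rats - cat_equivalence *
    n_cats)`` is evaluated on the grid; the 2.5/16/50/84/97.5 percentiles
    across draws border the decline/increase risk regions in phase space.
    """
    grid = np.asarray(list(cat_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("cat_grid must be non-empty")
    if (grid < 0).any():
        raise ValueError("cat_grid must be non-negative")
    draws = sample_parameters(specs, plan)
    out, _, viable = evaluate_draws(draws, eta_target)
    cr = out["critical_rats"].to_numpy()[viable]
    ce = out["cat_equivalence"].to_numpy()[viable]
    if cr.size == 0:
        raise RuntimeError("every Monte Carlo draw violated model preconditions")
    # draws x grid
    lines = np.maximum(cr[:, None] - ce[:, None] * grid[None, :], 0.0)
    q = np.percentile(lines, [2.5, 16.0, 50.0, 84.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "n_cats": grid,
            "q2p5": q[0],
            "q16": q[1],
            "q50": q[2],
            "q84": q[3],
            "q97p5": q[4],
        }
    )


def classify_scenario(
    band_table: pd.DataFrame, s: PredatorScenario
) -> str:
    """Risk-region label of a cat-rat scenario against the quantile bands.

    Linear interpolation between grid points; scenarios outside the grid
    are refused.  Points exactly on a border take the riskier (decline-side)
    label.
    """
    for col in _BAND_COLUMNS:
        if col not in band_table.columns:
            raise ValueError(f"band table is missing column {col!r}")
    grid = band_table["n_cats"].to_numpy(dtype=float)
    order = np.argsort(grid)
    grid = grid[order]
    if not grid[0] <= s.n_cats <= grid[-1]:
        raise ValueError(
            f"n_cats={s.n_cats} outside the band grid "
            f"[{grid[0]}, {grid[-1]}]; extrapolation refused"
        )
    at = {
        col: float(np.interp(s.n_cats, grid, band_table[col].to_numpy()[order]))
        for col in _BAND_COLUMNS[1:]
    }
    r = s.n_rats
    if r >= at["q97p5"]:
        return REGION_LABELS[0]
    if r >= at["q84"]:
        return REGION_LABELS[1]
    if r >= at["q50"]:
        return REGION_LABELS[2]
    if r >= at["q16"]:
        return REGION_LABELS[3]
    if r >= at["q2p5"]:
        return REGION_LABELS[4]
    return REGION_LABELS[5]
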