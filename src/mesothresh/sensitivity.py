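"""One-at-a-time sensitivity of cat equivalence.

Each eligible parameter is perturbed strongly (default 75%) while every
other parameter is held at its mean, and the resulting variation in cat
equivalence is recorded in two modes:

* deterministic endpoints at ``mean * (1 - v)`` and ``mean * (1 + v)``,
  clipped to the parameter's natural domain, and
* Monte Carlo draws from a truncated normal with ``sd = v * mean``
  (natural-domain truncation), summarised by the width of the central 95%
  interval of the cat-equivalence draws.

``N_A0``, ``beta`` and ``mu_A`` are excluded: cat equivalence is
algebraically independent of them.  Perturbing a primitive re-derives its
dependants (predator mass re-enters through metabolic demand, juvenile
mortality through hatchling mortality); the allometric regression constants
are not varied by default since a multiplicative 75% shift of a power-law
*exponent* rescales metabolic demand by several orders of magnitude, which
is not a comparable field uncertainty (set ``include_allometric=True`` to
rank them anyway).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .parameters import ParameterSpec
from .thresholds import thresholds_from_values

__all__ = ["SensitivityResult", "sensitivity_oat", "EXCLUDED_PARAMETERS"]

#: parameters on which cat equivalence does not depend
EXCLUDED_PARAMETERS = frozenset({"N_A0", "beta", "mu_A"})

#: derived rows re-computed when one of their primitives is perturbed
_PROPAGATION = {
    "mass_C": ("metdemand_C",),
    "mass_R": ("metdemand_R",),
    "mu_J": ("mu_H",),
    "allom_coeff_C": ("metdemand_C",),
    "allom_exp_C": ("metdemand_C",),
    "allom_coeff_R": ("metdemand_R",),
    "allom_exp_R": ("metdemand_R",),
}

_ALLOMETRIC = frozenset(
    {"allom_coeff_C", "allom_exp_C", "allom_coeff_R", "allom_exp_R"}
)


@dataclass(frozen=True)
class SensitivityResult:
    """Cat-equivalence variation caused by perturbing one parameter."""

    parameter: str
    endpoint_low: float    # cat equivalence at mean * (1 - variation)
    endpoint_high: float   # cat equivalence at mean * (1 + variation)
    endpoint_spread: float  # |range| spanned by the two endpoints
    mc_spread: float       # width of the central 95% interval under MC
    rank: int
    flagged: bool = False  # an endpoint left the model's valid domain


def _natural_domain(spec: ParameterSpec) -> tuple[float, float]:
    return spec.natural_low, spec.natural_high


def _recompute(values: dict, name: str) -> None:
    for dep in _PROPAGATION.get(name, ()):
        if dep == "metdemand_C":
            values[dep] = values["allom_coeff_C"] * values["mass_C"] ** values["allom_exp_C"]
        elif dep == "metdemand_R":
            values[dep] = values["allom_coeff_R"] * values["mass_R"] ** values["allom_exp_R"]
        elif dep == "mu_H":
            window = (values["T_B"] - values["T_I"]) / 365.0
            values[dep] = 1.0 - (1.0 - values["mu_J"]) ** window


def _cat_equivalence(values: dict, eta_target: float):
    _, ce, _, valid = thresholds_from_values(values, eta_target)
    return ce, valid


def sensitivity_oat(
    specs: Iterable[ParameterSpec],
    variation: float = 0.75,
    *,
    n_draws: int = 20_000,
    seed: int | None = None,
    eta_target: float = 1.0,
    rank_by: str = "endpoints",
    include_allometric: bool = False,
    parameters: Sequence[str] | None = None,
) -> list[SensitivityResult]:
    """Rank parameters by their one-at-a-time effect on cat equivalence.

    ``rank_by`` selects the spread used for the ranking: ``"endpoints"``
    (deterministic +/-variation shifts, the default) or ``"mc"`` (width of
    the central 95% interval under truncated-normal draws with
    ``sd = variation * mean``).  Both spreads are always reported.
    """
    if variation < 0:
        raise ValueError(f"variation must be >= 0, got {variation}")
    if rank_by not in ("endpoints", "mc"):
        raise ValueError(f"unknown rank_by {rank_by!r}")

    specs = list(specs)
    by_name = {s.name: s for s in specs}
    means = {s.name: s.mean for s in specs}

    if parameters is not None:
        eligible = [by_name[p] for p in parameters]
    else:
        eligible = [
            s for s in specs
            if s.name not in EXCLUDED_PARAMETERS
            and s.name not in ("alpha_M", "alpha_R")
            and (include_allometric or s.name not in _ALLOMETRIC)
        ]

    rng = np.random.default_rng(seed)
    results: list[SensitivityResult] = []
    for spec in eligible:
        lo_dom, hi_dom = _natural_domain(spec)
        flagged = False

        # deterministic endpoints
        endpoints = []
        for fac in (1.0 - variation, 1.0 + variation):
            v = dict(means)
            v[spec.name] = float(np.clip(spec.mean * fac, lo_dom, hi_dom))
            _recompute(v, spec.name)
            ce, valid = _cat_equivalence(v, eta_target)
            if not bool(np.all(valid)) or not np.isfinite(ce):
                flagged = True
                endpoints.append(np.nan)
            else:
                endpoints.append(float(ce))
        finite = [e for e in endpoints if np.isfinite(e)]
        base_ce, _ = _cat_equivalence(dict(means), eta_target)
        if not finite:
            endpoint_spread = np.nan
        elif len(finite) == 1:
            endpoint_spread = abs(finite[0] - float(base_ce))
        else:
            endpoint_spread = abs(endpoints[1] - endpoints[0])

        # Monte Carlo perturbation of this parameter alone
        if variation == 0.0 or n_draws < 2:
            mc_spread = 0.0 if variation == 0.0 else np.nan
        else:
            sd = variation * abs(spec.mean)
            a = (lo_dom - spec.mean) / sd
            b = (hi_dom - spec.mean) / sd if np.isfinite(hi_dom) else np.inf
            draws = stats.truncnorm.rvs(
                a, b, loc=spec.mean, scale=sd, size=n_draws, random_state=rng
            )
            v = {k: np.full(n_draws, val) for k, val in means.items()}
            v[spec.name] = draws
            _recompute(v, spec.name)
            ce, valid = _cat_equivalence(v, eta_target)
            ce = np.asarray(ce)[np.asarray(valid) & np.isfinite(ce)]
            if ce.size < 2:
                mc_spread = np.nan
                flagged = True
            else:
                qlo, qhi = np.percentile(ce, [2.5, 97.5])
                mc_spread = float(qhi - qlo)

        results.append(
            SensitivityResult(
                parameter=spec.name,
                endpoint_low=endpoints[0],
                endpoint_high=endpoints[1],
                endpoint_spread=float(endpoint_spread),
                mc_spread=float(mc_spread),
                rank=0,
                flagged=flagged,
            )
        )

    key = "endpoint_spread" if rank_by == "endpoints" else "mc_spread"
    order = sorted(
        range(len(results)),
        key=lambda i: (-(getattr(results[i], key)
                        if np.isfinite(getattr(results[i], key)) else -np.inf),
                       results[i].parameter),
    )
    ranked = [None] * len(results)
    for rank, i in enumerate(order, start=1):
        res = results[i]
        ranked[rank - 1] = SensitivityResult(
            parameter=res.parameter,
            endpoint_low=res.endpoint_low,
            endpoint_high=res.endpoint_high,
            endpoint_spread=res.endpoint_spread,
            mc_spread=res.mc_spread,
            rank=rank,
            flagged=res.flagged,
        )
    return ranked
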