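"""Model parameters: definition, validation, loading and derived quantities.

The model is parameterised by the red-tailed tropicbird's demography, the
predators' bioenergetics, and a handful of derived quantities (clutch size
per adult ``beta``, hatchling natural mortality over the nestling window
``mu_H``, years at sea before maturity ``T_mat``, hatchling mass, and the
allometric daily metabolic demands).  Packaged defaults reproduce the
Christmas Island case study; any value can be overridden from a YAML/JSON
mapping.
"""

from __future__ import annotations

import dataclasses
import functools
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, NamedTuple

import yaml

from .energetics import EnergeticsParams, metabolic_demand

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "ParameterSpec",
    "DemographyParams",
    "ParameterSet",
    "load_parameters",
    "default_config",
    "derive_beta",
    "derive_mu_H",
    "derive_T_mat",
    "derive_mass_H",
    "specs_to_frame",
]

log = logging.getLogger(__name__)


class ConfigurationError(KeyError):
    """A required primitive parameter is missing from the configuration."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


_PROPORTIONS = frozenset(
    {
        "nu",
        "mu_A",
        "mu_J",
        "mu_H",
        "preypref_A_C",
        "preypref_H_C",
        "preypref_H_R",
        "preypref_E_R",
    }
)

#: registry of every model parameter:
#: (units, kind, printed range, drawn in Monte Carlo?)
_REGISTRY: dict[str, tuple[str, str, tuple[float, float] | None, bool]] = {
    "N_A0": ("individuals", "primitive", None, True),
    "T_I": ("days", "temporal", None, False),
    "T_H": ("days", "temporal", None, False),
    "T_B": ("days", "temporal", None, False),
    "T_mat": ("years", "temporal", None, False),
    "alpha_M": ("years", "temporal", None, False),
    "alpha_R": ("years", "temporal", None, False),
    "beta": ("eggs adult^-1 season^-1", "derived", None, True),
    "nu": ("proportion", "primitive", None, True),
    "mu_A": ("proportion yr^-1", "primitive", (0.10, 0.15), True),
    "mu_J": ("proportion yr^-1", "primitive", None, True),
    "mu_H": ("proportion", "derived", None, True),
    "preypref_A_C": ("proportion", "primitive", None, True),
    "preypref_H_C": ("proportion", "primitive", None, True),
    "preypref_H_R": ("proportion", "primitive", None, True),
    "preypref_E_R": ("proportion", "primitive", None, True),
    "mass_C": ("g", "primitive", (2000.0, 4500.0), True),
    "mass_R": ("g", "primitive", (15.0, 250.0), True),
    "mass_A": ("g", "primitive", (600.0, 800.0), True),
    "mass_H": ("g", "derived", (300.0, 400.0), True),
    "mass_E": ("g", "primitive", None, True),
    "energy_A": ("kJ g^-1", "primitive", None, True),
    "energy_H": ("kJ g^-1", "primitive", None, True),
    "energy_E": ("kJ g^-1", "primitive", None, True),
    "allom_coeff_C": ("kJ g^-expo day^-1", "primitive", None, False),
    "allom_exp_C": ("dimensionless", "primitive", None, False),
    "allom_coeff_R": ("kJ g^-expo day^-1", "primitive", None, False),
    "allom_exp_R": ("dimensionless", "primitive", None, False),
    "metdemand_C": ("kJ day^-1", "derived", None, True),
    "metdemand_R": ("kJ day^-1", "derived", None, True),
}

_PRIMITIVE_KEYS = tuple(
    name for name, (_, kind, _r, _s) in _REGISTRY.items()
    if kind == "primitive" or (kind == "temporal" and name != "T_mat")
)


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: value, uncertainty metadata and natural domain.

    ``kind`` distinguishes primitives (read from configuration), derived
    rows (computed from primitives) and temporal rows (durations held fixed
    under uncertainty).  ``sampled`` marks the rows that are drawn in Monte
    Carlo propagation; ``cv`` is the default coefficient of variation of the
    truncated-normal draw.
    """

    name: str
    mean: float
    range_low: float | None = None
    range_high: float | None = None
    units: str = ""
    kind: str = "primitive"
    cv: float = 0.20
    sampled: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValidationError(f"{self.name}: mean must be finite, got {self.mean}")
        if self.cv < 0:
            raise ValidationError(f"{self.name}: cv must be >= 0, got {self.cv}")
        if (self.range_low is None) != (self.range_high is None):
            raise ValidationError(f"{self.name}: range must give both bounds")
        if self.range_low is not None:
            if not self.range_low <= self.mean <= self.range_high:
                raise ValidationError(
                    f"{self.name}: mean {self.mean} outside range "
                    f"[{self.range_low}, {self.range_high}]"
                )
        if self.name in _PROPORTIONS and not 0.0 <= self.mean <= 1.0:
            raise ValidationError(
                f"{self.name}: proportion must lie in [0, 1], got {self.mean}"
            )

    @property
    def natural_low(self) -> float:
        return 0.0

    @property
    def natural_high(self) -> float:
        return 1.0 if self.name in _PROPORTIONS else math.inf


@dataclass(frozen=True)
class DemographyParams:
    """Tropicbird life-cycle and natural-mortality parameters."""

    N_A0: float   # adult birds at breeding-season start [individuals]
    T_I: float    # incubation time [days]
    T_H: float    # hatchling nest time [days]
    T_B: float    # breeding-season duration [days]
    T_mat: float  # years juveniles spend at sea before maturity [years]
    alpha_M: float  # age at reproductive maturity [years]
    alpha_R: float  # life span [years]
    beta: float   # eggs laid per adult per season
    nu: float     # proportion of viable eggs
    mu_A: float   # annual adult natural mortality [proportion/yr]
    mu_J: float   # annual juvenile natural mortality [proportion/yr]
    mu_H: float   # hatchling natural mortality over the nestling window

    def __post_init__(self) -> None:
        if not self.N_A0 > 0:
            raise ValidationError(f"N_A0 must be > 0, got {self.N_A0}")
        for name in ("T_I", "T_H", "T_B", "T_mat"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.alpha_R > self.alpha_M > 0:
            raise ValidationError(
                f"need alpha_R > alpha_M > 0, got alpha_R={self.alpha_R}, "
                f"alpha_M={self.alpha_M}"
            )
        for name in ("mu_A", "mu_J", "mu_H", "nu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.beta < 0:
            raise ValidationError(f"beta must be >= 0, got {self.beta}")

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


class ParameterSet(NamedTuple):
    """Validated parameters plus the per-parameter specs used for sampling."""

    demography: DemographyParams
    energetics: EnergeticsParams
    specs: list[ParameterSpec]

    def values(self) -> dict[str, float]:
        """All parameter means keyed by name (one row per Table entry)."""
        return {s.name: s.mean for s in self.specs}


# --------------------------------------------------------------------------
# derived parameters
# --------------------------------------------------------------------------

def derive_beta(alpha_M: float, alpha_R: float) -> float:
    """Eggs laid per adult per season from the reproductive fraction of life.

    One egg per pair (0.5 per adult), discounted by the fraction of the
    life span spent immature: ``0.5 * (alpha_R - alpha_M) / alpha_R``.
    """
    if not alpha_R > alpha_M > 0:
        raise ValidationError(
            f"need alpha_R > alpha_M > 0, got alpha_M={alpha_M}, alpha_R={alpha_R}"
        )
    return 0.5 * (alpha_R - alpha_M) / alpha_R


def derive_mu_H(mu_J: float, T_B: float, T_I: float) -> float:
    """Hatchling natural mortality over the nestling window.

    Scales annual juvenile survival ``1 - mu_J`` to the ``T_B - T_I`` days a
    hatchling spends in the nest: ``1 - (1 - mu_J)**((T_B - T_I)/365)``.
    """
    if not 0.0 <= mu_J <= 1.0:
        raise ValidationError(f"mu_J must lie in [0, 1], got {mu_J}")
    if not T_B > T_I > 0:
        raise ValidationError(f"need T_B > T_I > 0, got T_B={T_B}, T_I={T_I}")
    if mu_J == 1.0:
        return 1.0
    return 1.0 - (1.0 - mu_J) ** ((T_B - T_I) / 365.0)


def _mu_H_over_window(mu_J: float, window_days: float) -> float:
    if not window_days > 0:
        raise ValidationError(f"window must be > 0, got {window_days}")
    if mu_J == 1.0:
        return 1.0
    return 1.0 - (1.0 - mu_J) ** (window_days / 365.0)


def derive_T_mat(alpha_M: float, T_B: float) -> float:
    """Years juveniles spend at sea: age at maturity minus the season ashore."""
    out = alpha_M - T_B / 365.0
    if not out > 0:
        raise ValidationError(
            f"T_mat must be > 0; alpha_M={alpha_M} y, T_B={T_B} d gives {out}"
        )
    if alpha_M > 10:
        log.warning(
            "derive_T_mat called with alpha_M=%.3g y; maturation ages above "
            "10 y suggest the life span was passed instead of the age at "
            "maturity", alpha_M,
        )
    return out


def derive_mass_H(mass_A: float) -> float:
    """Hatchling mass as half the adult mass."""
    if not mass_A > 0:
        raise ValidationError(f"mass_A must be > 0, got {mass_A}")
    return mass_A / 2.0


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _default_values() -> tuple[tuple[str, float], ...]:
    text = resources.files("mesothresh").joinpath("data/defaults.yaml").read_text()
    return tuple(yaml.safe_load(text).items())


def default_config() -> dict[str, float]:
    """The packaged default parameter means (Christmas Island case study)."""
    return dict(_default_values())


def _read_config(config: Any) -> dict[str, Any]:
    if config is None or config == "defaults":
        return {}
    if isinstance(config, Mapping):
        return dict(config)
    path = Path(config)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def load_parameters(
    config: Any = None,
    *,
    beta_mode: str = "corrected",
    muH_mode: str = "TB_minus_TI",
    catdiet_mode: str = "as_printed",
    cv: float = 0.20,
) -> ParameterSet:
    """Load, validate and derive the full parameter set.

    Parameters
    ----------
    config
        ``None``/``"defaults"`` for the packaged defaults, a mapping, or a
        path to a YAML/JSON document.  Any supplied key overrides the
        default (overrides of derived parameters are honoured and logged).
    beta_mode
        ``"corrected"`` derives beta from the reproductive life span;
        ``"override"`` requires an explicit ``beta`` in the configuration.
    muH_mode
        Window for hatchling natural mortality: ``"TB_minus_TI"`` (season
        minus incubation) or ``"TH"`` (the printed nestling time, which
        differs because the printed durations do not satisfy
        ``T_B = T_I + T_H``).
    catdiet_mode
        ``"as_printed"`` uses the published 0.382 bird fraction for both the
        adult and the hatchling component of cat diet; ``"split"`` divides
        it equally between the two stages (0.191 each).
    cv
        Default coefficient of variation attached to every sampled
        parameter spec.
    """
    if muH_mode not in ("TB_minus_TI", "TH"):
        raise ConfigurationError(f"unknown muH_mode {muH_mode!r}")
    if catdiet_mode not in ("as_printed", "split"):
        raise ConfigurationError(f"unknown catdiet_mode {catdiet_mode!r}")
    if beta_mode not in ("corrected", "override"):
        raise ConfigurationError(f"unknown beta_mode {beta_mode!r}")

    user = _read_config(config)
    ranges = dict(user.pop("ranges", {}))
    values = default_config()
    if catdiet_mode == "split":
        total = values["preypref_A_C"]
        values["preypref_A_C"] = total / 2.0
        values["preypref_H_C"] = total / 2.0

    overridden = sorted(set(user) & set(values))
    unknown = sorted(set(user) - set(_REGISTRY))
    if unknown:
        raise ConfigurationError(f"unknown parameter(s): {', '.join(unknown)}")
    values.update(user)
    for name in overridden:
        log.info("parameter override: %s = %s", name, values[name])

    missing = [k for k in _PRIMITIVE_KEYS if k not in values]
    if missing:
        raise ConfigurationError(f"missing primitive parameter(s): {', '.join(missing)}")

    # derived rows, unless explicitly overridden
    if beta_mode == "override" and "beta" not in values:
        raise ConfigurationError("beta_mode='override' requires an explicit beta")
    if "beta" not in values:
        values["beta"] = derive_beta(values["alpha_M"], values["alpha_R"])
    else:
        log.info("derived parameter beta overridden: %s", values["beta"])
    if "mu_H" not in values:
        if muH_mode == "TB_minus_TI":
            values["mu_H"] = derive_mu_H(values["mu_J"], values["T_B"], values["T_I"])
        else:
            values["mu_H"] = _mu_H_over_window(values["mu_J"], values["T_H"])
    else:
        log.info("derived parameter mu_H overridden: %s", values["mu_H"])
    if "T_mat" not in values:
        values["T_mat"] = derive_T_mat(values["alpha_M"], values["T_B"])
    if "mass_H" not in values:
        values["mass_H"] = derive_mass_H(values["mass_A"])
    if "metdemand_C" not in values:
        values["metdemand_C"] = metabolic_demand(
            values["mass_C"], values["allom_coeff_C"], values["allom_exp_C"]
        )
    if "metdemand_R" not in values:
        values["metdemand_R"] = metabolic_demand(
            values["mass_R"], values["allom_coeff_R"], values["allom_exp_R"]
        )

    demography = DemographyParams(
        **{k: float(values[k]) for k in (
            "N_A0", "T_I", "T_H", "T_B", "T_mat", "alpha_M", "alpha_R",
            "beta", "nu", "mu_A", "mu_J", "mu_H",
        )}
    )
    energetics = EnergeticsParams(
        **{k: float(values[k]) for k in (
            "mass_C", "mass_R", "mass_A", "mass_H", "mass_E",
            "energy_A", "energy_H", "energy_E",
            "preypref_A_C", "preypref_H_C", "preypref_H_R", "preypref_E_R",
            "allom_coeff_C", "allom_exp_C", "allom_coeff_R", "allom_exp_R",
        )}
    )

    specs: list[ParameterSpec] = []
    for name, (units, kind, printed, sampled) in _REGISTRY.items():
        rng = ranges.get(name, printed)
        lo, hi = (rng if rng is not None else (None, None))
        if lo is not None and not float(lo) <= float(values[name]) <= float(hi):
            log.info(
                "parameter %s=%s lies outside its printed range [%s, %s]; "
                "dropping the range", name, values[name], lo, hi,
            )
            lo, hi = None, None
        specs.append(
            ParameterSpec(
                name=name,
                mean=float(values[name]),
                range_low=None if lo is None else float(lo),
                range_high=None if hi is None else float(hi),
                units=units,
                kind=kind,
                cv=cv,
                sampled=sampled,
            )
        )

    _check_diet_budget(energetics)
    return ParameterSet(demography, energetics, specs)


def _check_diet_budget(e: EnergeticsParams) -> None:
    if e.preypref_A_C + e.preypref_H_C > 1.0 + 1e-12:
        raise ValidationError(
            "cat diet fractions exceed the daily intake budget: "
            f"{e.preypref_A_C} + {e.preypref_H_C} > 1"
        )
    if e.preypref_H_R + e.preypref_E_R > 1.0 + 1e-12:
        raise ValidationError(
            "rat diet fractions exceed the daily intake budget: "
            f"{e.preypref_H_R} + {e.preypref_E_R} > 1"
        )


def specs_to_frame(specs: Iterable[ParameterSpec]):
    """Tabulate parameter specs (one row per parameter) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(s) for s in specs]).set_index("name")
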