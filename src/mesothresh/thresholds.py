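"""Reproduction-ratio indicator and closed-form predation thresholds.

The persistence indicator ``eta`` compares the juveniles hatched in one
breeding season that survive to reproductive maturity against the loss of
the adult population over that same season; ``eta < 1`` predicts long-term
decline.  Setting ``eta`` to a target (default 1) yields a straight
threshold line in cat-rat phase space,

    n_rats = critical_rats - cat_equivalence * n_cats,

whose intercepts are the critical rat and cat abundances and whose slope
magnitude (cat equivalence) is the number of rats with the same marginal
effect on ``eta`` as one cat.

Three non-negativity constraints clamp the season's mass balance: cats
cannot eat more adults than exist, rats cannot eat more eggs than are laid,
and combined hatchling predation cannot exceed the eggs hatched.  The
closed forms hold in the unclamped region; ``summarize_thresholds`` warns
when a computed threshold falls outside it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .energetics import PredationRates
from .parameters import DemographyParams

__all__ = [
    "PredatorScenario",
    "ClampFlags",
    "BreedingOutcome",
    "ThresholdSummary",
    "InfiniteThresholdWarning",
    "ClampRegionWarning",
    "ModelDomainError",
    "breeding_outcome",
    "adult_loss",
    "juveniles_mature",
    "reproduction_ratio",
    "critical_rats",
    "cat_equivalence",
    "critical_cats",
    "threshold_line",
    "summarize_thresholds",
    "closed_form_thresholds",
    "thresholds_from_values",
]


class InfiniteThresholdWarning(UserWarning):
    """A predator exerts no predation, so its threshold abundance is infinite."""


class ClampRegionWarning(UserWarning):
    """A closed-form threshold lies where a non-negativity clamp binds."""


class ModelDomainError(ArithmeticError):
    """The indicator is undefined for these inputs (zero adult loss)."""


@dataclass(frozen=True)
class PredatorScenario:
    """A point in cat-rat phase space (real-valued abundances)."""

    n_cats: float
    n_rats: float

    def __post_init__(self) -> None:
        if self.n_cats < 0 or self.n_rats < 0:
            raise ValueError(
                f"predator abundances must be >= 0, got "
                f"({self.n_cats}, {self.n_rats})"
            )


@dataclass(frozen=True)
class ClampFlags:
    """Which non-negativity constraints bound in a season's mass balance."""

    eggs: bool = False
    hatchlings: bool = False
    adults: bool = False

    def any(self) -> bool:
        return self.eggs or self.hatchlings or self.adults


@dataclass(frozen=True)
class BreedingOutcome:
    """One season's mass balance at a given predator scenario."""

    adult_loss: float           # N_A0 - N_A1 [birds]
    eggs_surviving: float       # eggs left after rat predation
    hatchlings_recruited: float  # juveniles alive at nest departure
    juveniles_mature: float     # N_J3: survivors to reproductive maturity
    eta: float                  # reproduction ratio
    clamped: ClampFlags


@dataclass(frozen=True)
class ThresholdSummary:
    """Threshold metrics for a target reproduction ratio."""

    critical_rats: float    # eta = target at n_cats = 0
    cat_equivalence: float  # rats with the marginal effect of one cat
    critical_cats: float    # eta = target at n_rats = 0
    eta_target: float = 1.0
    in_closed_form_region: bool = True
    status: str = "ok"


# --------------------------------------------------------------------------
# season mass balance
# --------------------------------------------------------------------------

def breeding_outcome(
    d: DemographyParams, r: PredationRates, s: PredatorScenario
) -> BreedingOutcome:
    """Evaluate one breeding season's mass balance with all clamps."""
    cat_take_adults = s.n_cats * r.p_A_C * d.T_B
    adults_clamp = (1.0 - d.mu_A) * d.N_A0 - cat_take_adults < 0.0
    loss = d.N_A0 if adults_clamp else d.N_A0 * d.mu_A + cat_take_adults

    eggs_laid = d.beta * d.N_A0
    eggs_taken = s.n_rats * r.p_E_R * d.T_I
    eggs_clamp = eggs_taken > eggs_laid
    eggs_surviving = max(0.0, eggs_laid - eggs_taken)

    hatch_survivors = d.nu * eggs_surviving * (1.0 - d.mu_H)
    hatchling_take = (s.n_cats * r.p_H_C + s.n_rats * r.p_H_R) * d.T_H
    hatch_clamp = hatchling_take > hatch_survivors
    recruited = max(0.0, hatch_survivors - hatchling_take)

    mature = recruited * (1.0 - d.mu_J) ** d.T_mat

    if loss == 0.0:
        raise ModelDomainError(
            "adult loss is zero (mu_A = 0 and no cats); the reproduction "
            "ratio is undefined"
        )
    return BreedingOutcome(
        adult_loss=loss,
        eggs_surviving=eggs_surviving,
        hatchlings_recruited=recruited,
        juveniles_mature=mature,
        eta=mature / loss,
        clamped=ClampFlags(eggs=eggs_clamp, hatchlings=hatch_clamp,
                           adults=adults_clamp),
    )


def adult_loss(
    d: DemographyParams, r: PredationRates, s: PredatorScenario
) -> float:
    """Adult birds lost over the season (natural mortality + cat predation),
    clamped at the whole population."""
    cat_take = s.n_cats * r.p_A_C * d.T_B
    if (1.0 - d.mu_A) * d.N_A0 - cat_take < 0.0:
        return d.N_A0
    return d.N_A0 * d.mu_A + cat_take


def juveniles_mature(
    d: DemographyParams, r: PredationRates, s: PredatorScenario
) -> float:
    """Juveniles from this season's eggs surviving to reproductive maturity."""
    eggs_surviving = max(0.0, d.beta * d.N_A0 - s.n_rats * r.p_E_R * d.T_I)
    recruited = max(
        0.0,
        d.nu * eggs_surviving * (1.0 - d.mu_H)
        - (s.n_cats * r.p_H_C + s.n_rats * r.p_H_R) * d.T_H,
    )
    return recruited * (1.0 - d.mu_J) ** d.T_mat


def reproduction_ratio(
    d: DemographyParams, r: PredationRates, s: PredatorScenario
) -> float:
    """The persistence indicator ``eta`` at a predator scenario."""
    return breeding_outcome(d, r, s).eta


# --------------------------------------------------------------------------
# closed-form thresholds
# --------------------------------------------------------------------------

def closed_form_thresholds(
    *,
    N_A0,
    nu,
    beta,
    mu_A,
    mu_J,
    mu_H,
    T_mat,
    T_I,
    T_H,
    T_B,
    p_A_C,
    p_H_C,
    p_H_R,
    p_E_R,
    eta_target=1.0,
):
    """Vectorised closed forms for (critical_rats, cat_equivalence,
    critical_cats).

    All arguments broadcast; the rat-predation denominator must be positive
    (entries where it is not yield ``inf``/``nan`` and should be screened by
    the caller).  Negative critical-rat numerators are floored at zero.
    """
    grow = (1.0 - mu_J) ** (-T_mat)  # inverse juvenile survival to maturity
    with np.errstate(divide="ignore", invalid="ignore"):
        den = p_H_R * T_H + nu * (1.0 - mu_H) * p_E_R * T_I
        num = N_A0 * nu * beta * (1.0 - mu_H) - eta_target * N_A0 * mu_A * grow
        crit_rats = np.maximum(num / den, 0.0)
        cat_eq = (p_H_C * T_H + p_A_C * eta_target * T_B * grow) / den
        crit_cats = np.where(cat_eq > 0, crit_rats / cat_eq, np.inf)
    return crit_rats, cat_eq, crit_cats


def thresholds_from_values(values, eta_target=1.0):
    """Closed-form thresholds from a mapping of model-parameter values.

    ``values`` maps parameter names (as in the packaged defaults, including
    the derived rows ``metdemand_C``/``metdemand_R``/``mass_H``/``beta``/
    ``mu_H``) to scalars or broadcastable arrays.  Returns
    ``(critical_rats, cat_equivalence, critical_cats, valid)`` where
    ``valid`` flags entries with a positive rat-predation denominator.
    """
    v = values
    p_A_C = v["metdemand_C"] * v["preypref_A_C"] / (v["mass_A"] * v["energy_A"])
    p_H_C = v["metdemand_C"] * v["preypref_H_C"] / (v["mass_H"] * v["energy_H"])
    p_H_R = v["metdemand_R"] * v["preypref_H_R"] / (v["mass_H"] * v["energy_H"])
    p_E_R = v["metdemand_R"] * v["preypref_E_R"] / (v["mass_E"] * v["energy_E"])
    den = p_H_R * v["T_H"] + v["nu"] * (1.0 - v["mu_H"]) * p_E_R * v["T_I"]
    valid = np.asarray(den) > 0.0
    cr, ce, cc = closed_form_thresholds(
        N_A0=v["N_A0"], nu=v["nu"], beta=v["beta"], mu_A=v["mu_A"],
        mu_J=v["mu_J"], mu_H=v["mu_H"], T_mat=v["T_mat"], T_I=v["T_I"],
        T_H=v["T_H"], T_B=v["T_B"], p_A_C=p_A_C, p_H_C=p_H_C,
        p_H_R=p_H_R, p_E_R=p_E_R, eta_target=eta_target,
    )
    return cr, ce, cc, valid


def _unpack(d: DemographyParams, r: PredationRates) -> dict[str, float]:
    return dict(
        N_A0=d.N_A0, nu=d.nu, beta=d.beta, mu_A=d.mu_A, mu_J=d.mu_J,
        mu_H=d.mu_H, T_mat=d.T_mat, T_I=d.T_I, T_H=d.T_H, T_B=d.T_B,
        p_A_C=r.p_A_C, p_H_C=r.p_H_C, p_H_R=r.p_H_R, p_E_R=r.p_E_R,
    )


def _rat_denominator(d: DemographyParams, r: PredationRates) -> float:
    return r.p_H_R * d.T_H + d.nu * (1.0 - d.mu_H) * r.p_E_R * d.T_I


def critical_rats(
    d: DemographyParams, r: PredationRates, eta_target: float = 1.0
) -> float:
    """Maximum rat abundance sustaining ``eta >= eta_target`` with no cats.

    Floored at 0 when the population declines even without rats; infinite
    (with a warning) when rats exert no predation at all.
    """
    if _rat_denominator(d, r) <= 0.0:
        warnings.warn(
            "rats exert no predation on eggs or hatchlings; the critical rat "
            "abundance is infinite", InfiniteThresholdWarning, stacklevel=2,
        )
        return math.inf
    out, _, _ = closed_form_thresholds(**_unpack(d, r), eta_target=eta_target)
    return float(out)


def cat_equivalence(
    d: DemographyParams, r: PredationRates, eta_target: float = 1.0
) -> float:
    """Rats with the same marginal effect on ``eta`` as one cat.

    Zero when cats are harmless; infinite (with a warning) when rats exert
    no predation.  Algebraically independent of ``N_A0``, ``beta`` and
    ``mu_A``.
    """
    if _rat_denominator(d, r) <= 0.0:
        warnings.warn(
            "rats exert no predation; cat equivalence is infinite",
            InfiniteThresholdWarning, stacklevel=2,
        )
        return math.inf
    _, out, _ = closed_form_thresholds(**_unpack(d, r), eta_target=eta_target)
    return float(out)


def critical_cats(
    d: DemographyParams, r: PredationRates, eta_target: float = 1.0
) -> float:
    """Maximum cat abundance sustaining ``eta >= eta_target`` with no rats."""
    if _rat_denominator(d, r) <= 0.0:
        # rat-side denominators cancel in critical_rats / cat_equivalence
        return _critical_cats_direct(d, r, eta_target)
    ce = cat_equivalence(d, r, eta_target)
    if ce == 0.0:
        warnings.warn(
            "cats exert no predation; the critical cat abundance is infinite",
            InfiniteThresholdWarning, stacklevel=2,
        )
        return math.inf
    return critical_rats(d, r, eta_target) / ce


def _critical_cats_direct(
    d: DemographyParams, r: PredationRates, eta_target: float
) -> float:
    # limit of critical_rats / cat_equivalence as rat predation vanishes:
    # the rat-side denominators cancel.
    grow = (1.0 - d.mu_J) ** (-d.T_mat)
    num = d.N_A0 * d.nu * d.beta * (1.0 - d.mu_H) - eta_target * d.N_A0 * d.mu_A * grow
    den = r.p_H_C * d.T_H + r.p_A_C * eta_target * d.T_B * grow
    if den <= 0.0:
        warnings.warn(
            "cats exert no predation; the critical cat abundance is infinite",
            InfiniteThresholdWarning, stacklevel=2,
        )
        return math.inf
    return max(num / den, 0.0)


def threshold_line(
    d: DemographyParams,
    r: PredationRates,
    n_cats,
    eta_target: float = 1.0,
):
    """Maximum rat abundance keeping ``eta >= eta_target`` at ``n_cats``.

    Accepts a scalar or array of cat abundances; values are floored at 0.
    """
    cr = critical_rats(d, r, eta_target)
    ce = cat_equivalence(d, r, eta_target)
    out = np.maximum(cr - ce * np.asarray(n_cats, dtype=float), 0.0)
    return float(out) if np.isscalar(n_cats) or out.ndim == 0 else out


def summarize_thresholds(
    d: DemographyParams, r: PredationRates, eta_target: float = 1.0
) -> ThresholdSummary:
    """Critical rats, cat equivalence and critical cats, with a validity
    check that both intercepts lie where no clamp binds."""
    cr = critical_rats(d, r, eta_target)
    ce = cat_equivalence(d, r, eta_target)
    cc = critical_cats(d, r, eta_target)

    status = "ok"
    if cr == 0.0:
        status = "population not sustainable even without rats"
    elif math.isinf(cr):
        status = "rats exert no predation; rat thresholds are infinite"

    valid = True
    if math.isfinite(cr) and cr > 0.0:
        # egg clamp must not bind at the rat-axis intercept
        if d.beta * d.N_A0 - cr * r.p_E_R * d.T_I < 0.0:
            valid = False
    if math.isfinite(cc) and cc > 0.0:
        # adult clamp must not bind at the cat-axis intercept
        if (1.0 - d.mu_A) * d.N_A0 - cc * r.p_A_C * d.T_B < 0.0:
            valid = False
    if not valid:
        warnings.warn(
            "a closed-form threshold lies in the clamped region; the linear "
            "phase-space boundary is not exact there",
            ClampRegionWarning, stacklevel=2,
        )
    return ThresholdSummary(
        critical_rats=cr,
        cat_equivalence=ce,
        critical_cats=cc,
        eta_target=eta_target,
        in_closed_form_region=valid,
        status=status,
    )
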