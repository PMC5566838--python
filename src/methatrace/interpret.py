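"""Interpretation of paired CH3D / 14CH4 measurements.

The two tracers quantify different things: CH3D-derived rates measure
methane *activation* (initial C–H bond mobilization), 14CH4-derived rates
measure *full oxidation* to CO2/DIC. Their quotient — the D/14C tracer
ratio — is both a consistency check and a window into hydrogen routing:

* **activation-stoichiometric reading** (anaerobic, reverse methanogenesis):
  a ratio of ``n`` means ``n`` methane-derived hydrogens enter
  water-exchangeable intermediates per fully oxidized methane.
* **full-oxidation-complement reading** (aerobic): if all activation ends in
  full oxidation, a ratio ``r`` implies ``4/r`` of the four hydrogens reach
  water (a ratio of 1.5 → 2.67 H, the balance being shunted to biomass).

This module also bounds the enzymatic back-flux (re-formation of CH4 from
CH3D via reversible pathway steps, observed as growth of the CH4 fraction
in an initially pure-CH3D headspace), and compares method precision via
standard-error ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence


@dataclass(frozen=True)
class TracerRatioResult:
    """The D/14C tracer ratio (CH3D-derived over 14C-derived rate)."""

    ratio: float
    se: float = 0.0
    phase_or_condition: str = ""

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")

    @property
    def rounded(self) -> float:
        """Ratio at the 2-decimal reporting convention."""
        return round(self.ratio, 2)


@dataclass(frozen=True)
class ExchangeEstimate:
    """Implied count of water-exchangeable methane hydrogens (0..4)."""

    n_exchange: float
    model: Literal["activation_stoichiometric", "full_oxidation_complement"]

    def __post_init__(self):
        if not (0.0 <= self.n_exchange <= 4.0):
            raise ValueError("n_exchange must lie in [0, 4]")


@dataclass(frozen=True)
class BackfluxBounds:
    """Envelope for the fraction of initial CH3D re-formed as CH4.

    ``lower_percent`` assumes the whole oxidation pathway back-reacted
    (observed CH4 growth is the back-flux itself); ``upper_percent`` assumes
    only the methane-activating enzyme back-reacted, in which case only 1 in
    4 re-formed molecules swaps its D for H and appears as CH4, so the
    observed growth must be multiplied by 4. Both are scaled by the fraction
    of methane not fully oxidized (fully oxidized label cannot back-react).
    """

    delta_ch4_percent: float
    remaining_fraction: float
    lower_percent: float
    upper_percent: float

    def __post_init__(self):
        if self.lower_percent < 0 or self.upper_percent < 0:
            raise ValueError("bounds must be >= 0")
        if self.lower_percent > 0 and not math.isclose(
            self.upper_percent, 4.0 * self.lower_percent, rel_tol=1e-12
        ):
            raise ValueError("upper bound must be 4x the lower bound")

    @property
    def mcr_only_percent(self) -> float:
        """Headspace CH4 growth ×4: the activation-enzyme-only figure,
        before discounting fully oxidized methane."""
        return 4.0 * self.delta_ch4_percent


@dataclass(frozen=True)
class PrecisionComparison:
    """SE(CH3D)/SE(14C) and its reciprocal (fold precision advantage)."""

    se_ratio: float
    fold_precision: float

    def __post_init__(self):
        if self.se_ratio <= 0 or self.fold_precision <= 0:
            raise ValueError("ratios must be positive")


def tracer_ratio(
    chd_value: float,
    c14_value: float,
    se_chd: float = 0.0,
    se_c14: float = 0.0,
    phase: str = "",
    chd_time: float | None = None,
    c14_time: float | None = None,
) -> TracerRatioResult:
    """D/14C tracer ratio from paired measurements.

    Inputs may be rates (same units) or cumulative amounts. Amounts taken
    at different times are made comparable by dividing each by its own
    time (pass ``chd_time`` / ``c14_time``; any consistent unit). The SE
    uses first-order (delta-method) propagation assuming independence.
    """
    if c14_value == 0:
        raise ValueError("14C-derived value must be nonzero")
    if (chd_time is None) != (c14_time is None):
        raise ValueError("provide both times or neither")
    if chd_time is not None:
        if chd_time <= 0 or c14_time <= 0:
            raise ValueError("times must be > 0")
        chd_value, se_chd = chd_value / chd_time, se_chd / chd_time
        c14_value, se_c14 = c14_value / c14_time, se_c14 / c14_time
    ratio = chd_value / c14_value
    se = 0.0
    if se_chd or se_c14:
        se = abs(ratio) * math.hypot(se_chd / chd_value, se_c14 / c14_value)
    return TracerRatioResult(ratio=ratio, se=se, phase_or_condition=phase)


def full_oxidation_estimate(r_chd: float, scaling_factor: float) -> float:
    """Estimate of full-oxidation methanotrophy from an activation rate.

    Divides R_CH3D by an empirically determined D/14C tracer ratio for the
    system (e.g. ~1.5 for aerobic cultures, ~2 for anoxic seep material).
    """
    if scaling_factor <= 0:
        raise ValueError("scaling_factor must be > 0")
    return r_chd / scaling_factor


def exchangeable_hydrogens(
    ratio: float,
    model: Literal["activation_stoichiometric", "full_oxidation_complement"],
) -> ExchangeEstimate:
    """Map a tracer ratio to an implied exchangeable-hydrogen count.

    ``activation_stoichiometric``: n = ratio (each unit of excess activation
    signal over full oxidation is one exchanged hydrogen per oxidized
    methane). ``full_oxidation_complement``: n = 4/ratio (all activation is
    full oxidation; the signal deficit below 4 reflects hydrogens diverted
    to biomass). Values outside [0, 4] are capped at 4 with a warning —
    they diagnose a violated model rather than an input error.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if model == "activation_stoichiometric":
        n = ratio
    elif model == "full_oxidation_complement":
        if ratio < 1:
            raise ValueError("complement model requires ratio >= 1")
        n = 4.0 / ratio
    else:
        raise ValueError(f"unknown model {model!r}")
    if n > 4.0:
        warnings.warn(
            f"implied n_exchange {n:.3g} exceeds 4 (model assumption violated); "
            "capping at 4",
            stacklevel=2,
        )
        n = 4.0
    return ExchangeEstimate(n_exchange=n, model=model)


def backflux_bounds(
    f_ch4_t0: float, f_ch4_t1: float, fully_oxidized_percent: float
) -> BackfluxBounds:
    """Bound the percent of initial CH3D re-formed as CH4 by back-reaction.

    All arguments are percentages: CH4 headspace fraction at start and end,
    and the independently measured (14C) percent of methane fully oxidized
    over the same interval. Isotope effects and methanogenic CH4 production
    are neglected.
    """
    if f_ch4_t1 < f_ch4_t0 or f_ch4_t0 < 0:
        raise ValueError("require f_ch4_t1 >= f_ch4_t0 >= 0")
    if not (0.0 <= fully_oxidized_percent <= 100.0):
        raise ValueError("fully_oxidized_percent must be in [0, 100]")
    delta = f_ch4_t1 - f_ch4_t0
    remaining = 1.0 - fully_oxidized_percent / 100.0
    lower = delta * remaining
    return BackfluxBounds(
        delta_ch4_percent=delta,
        remaining_fraction=remaining,
        lower_percent=lower,
        upper_percent=4.0 * lower,
    )


def precision_comparison(se_chd: float, se_14c: float) -> PrecisionComparison:
    """Compare method precision via the ratio of standard errors."""
    if se_chd <= 0 or se_14c <= 0:
        raise ValueError("standard errors must be positive")
    r = se_chd / se_14c
    return PrecisionComparison(se_ratio=r, fold_precision=1.0 / r)


def aggregate_ratios(ratios: Sequence[float]) -> tuple[float, float]:
    """Mean and SE (sd/√n, n−1 variance) of a set of tracer ratios."""
    n = len(ratios)
    if n < 1:
        raise ValueError("no ratios")
    mean = sum(ratios) / n
    if n == 1:
        return mean, 0.0
    var = sum((x - mean) ** 2 for x in ratios) / (n - 1)
    return mean, math.sqrt(var / n)
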