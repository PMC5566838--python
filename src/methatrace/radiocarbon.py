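"""Full methane-oxidation rates from the 14CH4 radiotracer partition.

A trace of 14CH4 is added to a headspace-free incubation; at the end point
the residual labeled methane is combusted to 14CO2 and counted, and the
oxidized product pool (14C-DIC) is acidified, trapped and counted. The
oxidized fraction of the label times the (unlabeled) initial methane
inventory gives moles of methane fully oxidized:

    rate = [14CO2 / (14CH4 + 14CO2)] × CH4_initial / (volume × time)

reported in nmol cm⁻³ d⁻¹. Using the initial methane inventory (rather than
final) makes the rate insensitive to methane produced by methanogenesis
during the incubation. The initial inventory comes either from GC
quantification against gas standards or is declared directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

from .chd import HOURS_PER_DAY, RateEstimate

GAS_CONSTANT = 8.314  # J mol^-1 K^-1


@dataclass(frozen=True)
class RadiocarbonMeasurement:
    """End-point scintillation activities for one incubation.

    ``activity_14ch4`` is the sum over the two combustion trap vials;
    ``activity_14co2`` is the acidified-DIC trap. Bq throughout.
    """

    incubation_id: str
    activity_14co2: float
    activity_14ch4: float
    incubation_time: float  # days
    inoculum_volume: float  # cm^3

    def __post_init__(self):
        if self.activity_14co2 < 0 or self.activity_14ch4 < 0:
            raise ValueError("activities must be >= 0")
        if self.activity_14co2 + self.activity_14ch4 <= 0:
            raise ValueError("total activity must be > 0")
        if self.incubation_time <= 0 or self.inoculum_volume <= 0:
            raise ValueError("time and volume must be > 0")

    @property
    def oxidized_fraction(self) -> float:
        """Fraction of recovered label present as oxidized product."""
        return self.activity_14co2 / (self.activity_14co2 + self.activity_14ch4)


@dataclass(frozen=True)
class GcCalibration:
    """Linear GC response calibration through gas standards.

    ``anchors`` are (known concentration ppm, detector response) pairs; the
    fitted line is response = slope × ppm + intercept (not forced through
    the origin).
    """

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise ValueError("need at least two calibration anchors")
        if len({c for c, _ in self.anchors}) < 2:
            raise ValueError("anchors must span distinct concentrations")

    @property
    def fit(self) -> tuple[float, float]:
        """(slope, intercept) of response vs concentration."""
        xs = [c for c, _ in self.anchors]
        ys = [r for _, r in self.anchors]
        n = len(xs)
        mx, my = sum(xs) / n, sum(ys) / n
        sxx = sum((x - mx) ** 2 for x in xs)
        slope = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / sxx
        return slope, my - slope * mx


@dataclass(frozen=True)
class Ch4Inventory:
    """Initial methane inventory of an incubation, in mol."""

    total_ch4: float
    source: Literal["gc_measured", "declared"] = "declared"

    def __post_init__(self):
        if self.total_ch4 <= 0:
            raise ValueError("total_ch4 must be > 0")


def gc_concentration(response: float, cal: GcCalibration) -> float:
    """Invert a GC detector response to a methane concentration (ppm).

    A response outside the calibrated span triggers an extrapolation
    warning (the two-point line is only trusted between its anchors).
    """
    slope, intercept = cal.fit
    lo = min(r for _, r in cal.anchors)
    hi = max(r for _, r in cal.anchors)
    if not (lo <= response <= hi):
        warnings.warn(
            f"GC response {response} outside calibrated span [{lo}, {hi}]; "
            "extrapolating",
            stacklevel=2,
        )
    return (response - intercept) / slope


def headspace_moles(partial_pressure: float, gas_volume: float, temperature: float) -> float:
    """Ideal-gas moles from partial pressure (Pa), volume (m³), T (K)."""
    if partial_pressure <= 0 or gas_volume <= 0 or temperature <= 0:
        raise ValueError("pressure, volume and temperature must all be > 0")
    return partial_pressure * gas_volume / (GAS_CONSTANT * temperature)


def recovery_adjust(activity: float, recovery: float = 0.98, enabled: bool = False) -> float:
    """Optionally correct a trapped activity for incomplete recovery.

    The acid-trap procedure recovers ~98% of CO2 on average; the rate
    equation as used applies no correction, so the default is off.
    """
    if not (0.0 < recovery <= 1.0):
        raise ValueError("recovery must be in (0, 1]")
    return activity / recovery if enabled else activity


def rate_14c(
    m: RadiocarbonMeasurement,
    ch4: Ch4Inventory,
    blank: RadiocarbonMeasurement | None = None,
) -> RateEstimate:
    """Full methane-oxidation rate from a 14C label partition.

    Invariant to uniform rescaling of both activities (specific-activity
    independence). An optional blank measurement's oxidized fraction is
    subtracted before scaling (default: no blank).
    """
    frac = m.oxidized_fraction
    if blank is not None:
        frac = frac - blank.oxidized_fraction
    oxidized_nmol = frac * ch4.total_ch4 * 1e9
    value = oxidized_nmol / (m.inoculum_volume * m.incubation_time)
    return RateEstimate(
        value=value,
        se=0.0,
        interval=(0.0, m.incubation_time * HOURS_PER_DAY),
        method="C14",
        cumulative_nmol=oxidized_nmol,
    )


def rates_14c_replicates(
    measurements: Sequence[RadiocarbonMeasurement], ch4: Ch4Inventory
) -> list[RateEstimate]:
    """Vectorized convenience over replicate measurements."""
    return [rate_14c(m, ch4) for m in measurements]
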