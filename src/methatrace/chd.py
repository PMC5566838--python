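"""Methane-activation rates from aqueous D/H time series (CH3D tracer).

The monodeuterated-methane method supplies CH3D in the incubation headspace
and tracks deuterium appearing in the water phase. The calculus:

1. hydrogen inventory of the water phase, ``H = V_water [L] × 55.5 mol/L × 2``;
2. newly appeared deuterium between two time points,
   ``D_new = (D/H_T2 − D/H_T1) × H`` (the hydrogen pool is treated as constant
   between time points — the enrichments involved are ppm-level);
3. maximum methane activated, ``C = D_new × 4`` — the ×4 is the end-member in
   which only one of a methane molecule's four hydrogens reaches a
   water-exchangeable product, so each observed D stands for (at most) four
   activated methane molecules given CH3D's 1:3 D:H stoichiometry;
4. headspace correction, ``C_corr = C / f_CH3D`` where ``f_CH3D`` is the
   fraction of the methane headspace that is CH3D;
5. the rate, ``R_CH3D = C_corr × 1e9 / (t_days × V_inoculum_cm3)`` in
   nmol cm⁻³ d⁻¹.

No kinetic fractionation factor is applied by default (the relevant enzyme
isotope effects are poorly constrained); a pass-through multiplier is
available for sensitivity analysis. Killed-control subtraction and
replicate aggregation are provided; negative rates are never clamped, as
killed-control scatter legitimately dips below zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

#: moles of water per liter (55.5) times 2 hydrogen atoms per molecule.
MOL_H_PER_LITER = 55.5 * 2.0

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class IncubationSpec:
    """Geometry and tracer composition of one incubation.

    ``inoculum_volume`` is the rate denominator: the volume of consolidated
    sediment, rock or liquid culture, in cm³ (added water excluded for
    sediment/rock incubations). ``f_ch3d`` is the fraction of the methane
    headspace that is CH3D. ``sampled_aliquots`` records removed-and-replaced
    sampling events as (time_h, volume_liters) pairs.
    """

    incubation_id: str
    water_volume: float  # liters
    inoculum_volume: float  # cm^3
    f_ch3d: float
    headspace: dict[str, float] = field(default_factory=dict)  # gas -> Pa
    is_killed_control: bool = False
    replicate_group: str = ""
    sampled_aliquots: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.water_volume <= 0:
            raise ValueError("water_volume must be > 0")
        if self.inoculum_volume <= 0:
            raise ValueError("inoculum_volume must be > 0")
        if not (0.0 < self.f_ch3d <= 1.0):
            raise ValueError("f_ch3d must be in (0, 1]")


@dataclass(frozen=True)
class DhTimeseries:
    """Calibrated aqueous D/H observations over time for one incubation."""

    incubation_id: str
    points: tuple[tuple[float, float, float], ...]  # (time_h, d_h, se)

    def __post_init__(self):
        times = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(p[1] <= 0 for p in self.points):
            raise ValueError("D/H ratios must be positive")

    @property
    def times(self) -> list[float]:
        return [p[0] for p in self.points]


@dataclass(frozen=True)
class RateEstimate:
    """A methane rate in nmol cm⁻³ d⁻¹ with uncertainty and provenance."""

    value: float
    se: float
    interval: tuple[float, float]  # hours
    method: Literal["CH3D", "C14"]
    cumulative_nmol: float = 0.0

    def __post_init__(self):
        if self.interval[1] <= self.interval[0]:
            raise ValueError("interval must be nonempty")
        if self.se < 0:
            raise ValueError("se must be >= 0")


def hydrogen_inventory(spec: IncubationSpec) -> float:
    """Moles of hydrogen (H + D) in the incubation's water phase."""
    return spec.water_volume * MOL_H_PER_LITER


def d_new(dh_t1: float, dh_t2: float, h_moles: float) -> float:
    """Moles of newly appeared aqueous deuterium between two time points.

    Negative values are permitted (measurement noise) and sign-preserved.
    """
    if h_moles <= 0:
        raise ValueError("h_moles must be > 0")
    if dh_t1 <= 0 or dh_t2 <= 0:
        raise ValueError("D/H ratios must be positive")
    return (dh_t2 - dh_t1) * h_moles


def methane_activated(d_new_mol: float, stoichiometric_factor: float = 4.0) -> float:
    """Maximum moles of methane activated implied by D_new.

    The default factor 4 assumes a single hydrogen per activated molecule
    reaches water (so only 1 in 4 carries the D label) — the maximum-count
    end member. Pass ``4/n`` for a scenario with ``n`` exchangeable
    hydrogens.
    """
    if stoichiometric_factor < 1:
        raise ValueError("stoichiometric_factor must be >= 1")
    return d_new_mol * stoichiometric_factor


def headspace_correct(c: float, f_ch3d: float) -> float:
    """Scale activated methane from the CH3D fraction to total methane."""
    if not (0.0 < f_ch3d <= 1.0):
        raise ValueError("f_ch3d must be in (0, 1]")
    return c / f_ch3d


def rate_chd(
    c_corr: float,
    time_days: float,
    volume_cm3: float,
    interval_h: tuple[float, float] | None = None,
    se: float = 0.0,
) -> RateEstimate:
    """Maximum methane-consumption rate R_CH3D in nmol cm⁻³ d⁻¹."""
    if time_days <= 0:
        raise ValueError("time must be > 0")
    if volume_cm3 <= 0:
        raise ValueError("volume must be > 0")
    if interval_h is None:
        interval_h = (0.0, time_days * HOURS_PER_DAY)
    cumulative_nmol = c_corr * 1e9
    return RateEstimate(
        value=cumulative_nmol / (time_days * volume_cm3),
        se=se,
        interval=interval_h,
        method="CH3D",
        cumulative_nmol=cumulative_nmol,
    )


def sampling_replacement_adjust(
    series: DhTimeseries,
    spec: IncubationSpec,
    mode: Literal["paper_approximation", "exact_bookkeeping"] = "paper_approximation",
    alpha: float = 1.0,
) -> list[tuple[float, float]]:
    """Cumulative D_new (mol) at each time point after T0.

    ``paper_approximation`` treats the hydrogen pool as constant and ignores
    deuterium carried away in sampled-and-replaced aliquots:
    ``D_new(t) = (D/H(t) − D/H(0)) × H``.

    ``exact_bookkeeping`` additionally credits the deuterium excess removed
    with each aliquot (aliquot volume × 55.5 × 2 × (D/H at removal − baseline);
    replacement medium is assumed to carry the baseline ratio, since abiotic
    methane-water hydrogen exchange is negligible).

    ``alpha`` is a pass-through fractionation multiplier applied to the
    result (default 1.0 — no fractionation correction).

    Returns (time_h, cumulative D_new mol) for every point after the first.
    """
    if len(series.points) < 2:
        raise ValueError("need at least two time points")
    h = hydrogen_inventory(spec)
    t0, r0, _ = series.points[0]
    for t_al, v_al in spec.sampled_aliquots:
        if v_al >= spec.water_volume:
            raise ValueError("aliquot volume must be smaller than water volume")
        if not (series.points[0][0] <= t_al <= series.points[-1][0]):
            raise ValueError("aliquot time outside series span")

    out: list[tuple[float, float]] = []
    for t, r, _se in series.points[1:]:
        dnew = d_new(r0, r, h)
        if mode == "exact_bookkeeping":
            for t_al, v_al in spec.sampled_aliquots:
                if t_al <= t:
                    r_al = _interp_ratio(series, t_al)
                    dnew += (r_al - r0) * v_al * MOL_H_PER_LITER
        elif mode != "paper_approximation":
            raise ValueError(f"unknown mode {mode!r}")
        out.append((t, dnew * alpha))
    return out


def _interp_ratio(series: DhTimeseries, t: float) -> float:
    pts = series.points
    for (ta, ra, _), (tb, rb, _) in zip(pts, pts[1:]):
        if ta <= t <= tb:
            w = 0.0 if tb == ta else (t - ta) / (tb - ta)
            return ra + w * (rb - ra)
    raise ValueError("time outside series span")


def rates_from_series(
    series: DhTimeseries,
    spec: IncubationSpec,
    stoichiometric_factor: float = 4.0,
    alpha: float = 1.0,
    baseline: Literal["cumulative", "interval"] = "cumulative",
    aliquot_mode: Literal["paper_approximation", "exact_bookkeeping"] = "paper_approximation",
) -> list[RateEstimate]:
    """Full per-timepoint rate calculus for one incubation.

    ``baseline='cumulative'`` derives each rate from the change since T0
    (the default reading of "maximum moles consumed"); ``'interval'`` uses
    consecutive differences. SE is propagated from the D/H standard errors
    of the two endpoints in quadrature.
    """
    h = hydrogen_inventory(spec)
    dnew_series = sampling_replacement_adjust(series, spec, aliquot_mode, alpha)
    t0, r0, se0 = series.points[0]
    out: list[RateEstimate] = []
    prev_dnew = 0.0
    prev_t, prev_se = t0, se0
    for (t, cum_dnew), (_, _r, se_t) in zip(dnew_series, series.points[1:]):
        if baseline == "cumulative":
            dn, t_start, se_ref = cum_dnew, t0, se0
            dt_h = t - t0
        elif baseline == "interval":
            dn, t_start, se_ref = cum_dnew - prev_dnew, prev_t, prev_se
            dt_h = t - prev_t
        else:
            raise ValueError(f"unknown baseline mode {baseline!r}")
        c = methane_activated(dn, stoichiometric_factor)
        c_corr = headspace_correct(c, spec.f_ch3d)
        t_days = dt_h / HOURS_PER_DAY
        # propagate D/H SEs through the linear chain
        se_dh = math.hypot(se_ref, se_t)
        se_rate = (
            se_dh * h * alpha * stoichiometric_factor / spec.f_ch3d * 1e9
            / (t_days * spec.inoculum_volume)
        )
        out.append(
            rate_chd(c_corr, t_days, spec.inoculum_volume, (t_start, t), se_rate)
        )
        prev_dnew, prev_t, prev_se = cum_dnew, t, se_t
    return out


def subtract_killed_control(
    sample: RateEstimate, killed: Sequence[RateEstimate]
) -> RateEstimate:
    """Subtract the mean killed-control rate; SEs combine in quadrature.

    Negative results are retained — clamping would bias replicate means.
    """
    if not killed:
        raise ValueError("killed-control sequence is empty")
    if any(k.method != sample.method for k in killed):
        raise ValueError("method mismatch between sample and killed controls")
    n = len(killed)
    mean_k = sum(k.value for k in killed) / n
    mean_k_nmol = sum(k.cumulative_nmol for k in killed) / n
    if n > 1:
        var_k = sum((k.value - mean_k) ** 2 for k in killed) / (n - 1)
        se_k = math.sqrt(var_k / n)
    else:
        se_k = killed[0].se
    return RateEstimate(
        value=sample.value - mean_k,
        se=math.hypot(sample.se, se_k),
        interval=sample.interval,
        method=sample.method,
        cumulative_nmol=sample.cumulative_nmol - mean_k_nmol,
    )


def aggregate_replicates(estimates: Sequence[RateEstimate]) -> RateEstimate:
    """Mean and SE (sd/√n, n−1 variance) across biological replicates."""
    if not estimates:
        raise ValueError("no estimates to aggregate")
    first = estimates[0]
    if any(e.interval != first.interval or e.method != first.method for e in estimates):
        raise ValueError("mixed intervals or methods in replicate aggregation")
    n = len(estimates)
    mean = sum(e.value for e in estimates) / n
    mean_nmol = sum(e.cumulative_nmol for e in estimates) / n
    if n == 1:
        warnings.warn("single replicate: SE set to 0", stacklevel=2)
        se = 0.0
    else:
        var = sum((e.value - mean) ** 2 for e in estimates) / (n - 1)
        se = math.sqrt(var / n)
    return RateEstimate(
        value=mean,
        se=se,
        interval=first.interval,
        method=first.method,
        cumulative_nmol=mean_nmol,
    )
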