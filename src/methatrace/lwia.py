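"""Processing of raw liquid-water isotope analyzer (LWIA) injection data.

Cavity ring-down / off-axis ICOS water isotope analyzers report a per-injection
δD on an instrument-internal scale. Two artifacts dominate raw data quality:

* **memory** — carry-over of the previous analyte into the first injections of
  each round, remedied by discarding early injections and keeping only the
  last few of every round;
* **drift** — slow change of the instrument response over a run, remedied by
  re-measuring two waters of known isotopic composition periodically and
  re-deriving a two-point linear normalization to the VSMOW scale.

This module implements that protocol: positional quality filtering
(last ``keep_last`` injections per round, default 5 of 10), exclusion of
injections acquired under unstable instrument conditions (internal temperature
changing faster than 0.3 °C/h, or rising measurement-cell pressure),
segment-wise two-point VSMOW normalization re-anchored every
``segment_size`` injections (default 40), and per-sample aggregation to a
mean D/H ratio with a standard error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import CalibrationError, QCError

#: VSMOW reference D/H ratio (dimensionless). δD = 0‰ corresponds to this.
R_VSMOW = 155.76e-6

#: Maximum tolerated internal temperature drift during an analysis, °C per h.
TEMP_CHANGE_LIMIT = 0.3


@dataclass(frozen=True)
class InjectionRecord:
    """One LWIA injection.

    Parameters
    ----------
    sample_id:
        Identifier of the analyte (a sample or a standard water).
    round_index:
        1-based index of the round of injections this injection belongs to.
        Rounds are per-analyte: the protocol runs several rounds of
        consecutive injections for each analyte.
    injection_index:
        1-based position within the round (1..injections-per-round).
    raw_delta_d:
        δD on the instrument's internal scale, permil.
    temp_change_rate:
        Instrument internal temperature drift during the analysis, °C/h.
        ``None`` if the export carries no diagnostics (treated as passing).
    pressure_rising:
        True if the measurement-cell pressure was rising during the analysis.
        ``None`` if unknown (treated as passing).
    global_position:
        1-based position in the whole run; used for calibration segmentation.
    """

    sample_id: str
    round_index: int
    injection_index: int
    raw_delta_d: float
    temp_change_rate: float | None = None
    pressure_rising: bool | None = None
    global_position: int = 1

    def __post_init__(self):
        if self.round_index < 1 or self.injection_index < 1:
            raise ValueError("round_index and injection_index must be >= 1")
        if self.global_position < 1:
            raise ValueError("global_position must be >= 1")

    def passes_diagnostics(self, temp_limit: float = TEMP_CHANGE_LIMIT) -> bool:
        """True if instrument diagnostics permit using this injection."""
        if self.temp_change_rate is not None and self.temp_change_rate > temp_limit:
            return False
        if self.pressure_rising:
            return False
        return True


@dataclass(frozen=True)
class IsotopeStandard:
    """A water standard of known isotopic composition (δD on VSMOW scale)."""

    standard_id: str
    known_delta_d: float

    def __post_init__(self):
        if not math.isfinite(self.known_delta_d):
            raise ValueError("known_delta_d must be finite")


@dataclass
class AnalysisRun:
    """An ordered LWIA run: interleaved sample and standard injections."""

    injections: list[InjectionRecord]
    standards: Mapping[str, IsotopeStandard] = field(default_factory=dict)

    def __post_init__(self):
        positions = [inj.global_position for inj in self.injections]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("global_position must be strictly increasing")

    @property
    def sample_ids(self) -> list[str]:
        """Distinct non-standard analyte ids in run order."""
        seen: dict[str, None] = {}
        for inj in self.injections:
            if inj.sample_id not in self.standards:
                seen.setdefault(inj.sample_id, None)
        return list(seen)


@dataclass(frozen=True)
class CalibrationSegment:
    """A two-point linear map raw δD → VSMOW δD over a span of positions.

    The span ``[start_position, end_position)`` is half-open on global
    injection position.  ``calibrated = intercept + slope * raw``.
    """

    start_position: int
    end_position: int
    slope: float
    intercept: float

    def __post_init__(self):
        if self.end_position <= self.start_position:
            raise ValueError("empty segment span")
        if not math.isfinite(self.slope) or self.slope == 0.0:
            raise ValueError("slope must be finite and nonzero")

    def covers(self, global_position: int) -> bool:
        return self.start_position <= global_position < self.end_position


@dataclass(frozen=True)
class SampleMeasurement:
    """Aggregated, VSMOW-normalized measurement for one sample."""

    sample_id: str
    mean_delta_d: float  # permil VSMOW
    mean_d_h: float  # dimensionless
    se_d_h: float  # dimensionless
    n_used: int

    def __post_init__(self):
        if self.n_used < 1:
            raise ValueError("n_used must be >= 1")
        if self.se_d_h < 0:
            raise ValueError("se_d_h must be >= 0")


def qc_filter(
    run: AnalysisRun,
    keep_last: int = 5,
    temp_limit: float = TEMP_CHANGE_LIMIT,
) -> list[InjectionRecord]:
    """Apply positional and diagnostic quality control to a run.

    Per (analyte, round), only the final ``keep_last`` injections are kept
    (the memory-effect remedy); from those, any injection whose internal
    temperature changed faster than ``temp_limit`` °C/h or whose cell
    pressure was rising is removed. Relative order is preserved.

    Raises
    ------
    QCError
        If any analyte present in the run ends up with zero retained
        injections (never silently omitted).
    """
    if not run.injections:
        raise ValueError("run is empty")
    if keep_last < 1:
        raise ValueError("keep_last must be >= 1")

    # last keep_last of each (analyte, round), by injection_index
    by_round: dict[tuple[str, int], list[InjectionRecord]] = {}
    for inj in run.injections:
        by_round.setdefault((inj.sample_id, inj.round_index), []).append(inj)

    keep: set[int] = set()
    for members in by_round.values():
        tail = sorted(members, key=lambda r: r.injection_index)[-keep_last:]
        keep.update(id(r) for r in tail)

    retained = [
        inj
        for inj in run.injections
        if id(inj) in keep and inj.passes_diagnostics(temp_limit)
    ]

    wanted = {inj.sample_id for inj in run.injections}
    got = {inj.sample_id for inj in retained}
    missing = wanted - got
    if missing:
        raise QCError(missing)
    return retained


def qc_exclusions(
    run: AnalysisRun,
    keep_last: int = 5,
    temp_limit: float = TEMP_CHANGE_LIMIT,
) -> list[tuple[InjectionRecord, str]]:
    """Every excluded injection with the rule that triggered its exclusion.

    Rules, in precedence order: ``early_injection`` (not among the last
    ``keep_last`` of its round), ``temp_change`` (internal temperature
    drift above the limit), ``pressure_rising``. Each excluded injection
    appears exactly once.
    """
    by_round: dict[tuple[str, int], list[InjectionRecord]] = {}
    for inj in run.injections:
        by_round.setdefault((inj.sample_id, inj.round_index), []).append(inj)
    tail_ids: set[int] = set()
    for members in by_round.values():
        tail = sorted(members, key=lambda r: r.injection_index)[-keep_last:]
        tail_ids.update(id(r) for r in tail)

    out: list[tuple[InjectionRecord, str]] = []
    for inj in run.injections:
        if id(inj) not in tail_ids:
            out.append((inj, "early_injection"))
        elif inj.temp_change_rate is not None and inj.temp_change_rate > temp_limit:
            out.append((inj, "temp_change"))
        elif inj.pressure_rising:
            out.append((inj, "pressure_rising"))
    return out


def build_calibration_segments(
    run: AnalysisRun,
    segment_size: int = 40,
    keep_last: int = 5,
    temp_limit: float = TEMP_CHANGE_LIMIT,
) -> list[CalibrationSegment]:
    """Partition a run into calibration segments and fit their scale maps.

    Global positions ``1..N`` are split into consecutive spans of at most
    ``segment_size`` injections (standards included in the count, matching a
    protocol that re-measures standards after every ``segment_size``
    injections). Within each segment the retained injections (same
    last-``keep_last`` rule) of each standard are averaged, and the linear
    map from measured to known δD is solved. With exactly two standards this
    is the exact two-point line; with more, an ordinary least-squares line.

    Raises
    ------
    CalibrationError
        If a segment contains fewer than two distinct standards.
    """
    if not run.injections:
        raise ValueError("run is empty")
    if len(run.standards) < 2:
        raise CalibrationError("at least two standards are required")

    retained = _retained_standard_injections(run, keep_last, temp_limit)

    n = run.injections[-1].global_position
    segments: list[CalibrationSegment] = []
    start = 1
    while start <= n:
        end = min(start + segment_size, n + 1)
        in_seg = [r for r in retained if start <= r.global_position < end]
        by_std: dict[str, list[float]] = {}
        for r in in_seg:
            by_std.setdefault(r.sample_id, []).append(r.raw_delta_d)
        missing = sorted(set(run.standards) - set(by_std))
        if missing:
            raise CalibrationError(
                f"segment [{start}, {end}) is missing standard(s): "
                + ", ".join(missing)
            )
        measured = []
        known = []
        for std_id, values in sorted(by_std.items()):
            measured.append(sum(values) / len(values))
            known.append(run.standards[std_id].known_delta_d)
        slope, intercept = _fit_line(measured, known)
        segments.append(CalibrationSegment(start, end, slope, intercept))
        start = end
    return segments


def _retained_standard_injections(run, keep_last, temp_limit):
    """Last-keep_last + diagnostics filter applied to standard rounds only."""
    by_round: dict[tuple[str, int], list[InjectionRecord]] = {}
    for inj in run.injections:
        if inj.sample_id in run.standards:
            by_round.setdefault((inj.sample_id, inj.round_index), []).append(inj)
    out: list[InjectionRecord] = []
    for members in by_round.values():
        tail = sorted(members, key=lambda r: r.injection_index)[-keep_last:]
        out.extend(r for r in tail if r.passes_diagnostics(temp_limit))
    out.sort(key=lambda r: r.global_position)
    return out


def _fit_line(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    if len(x) == 2:
        if x[1] == x[0]:
            raise CalibrationError("standards have identical measured values")
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return slope, y[0] - slope * x[0]
    # >2 standards: ordinary least squares
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    if sxx == 0:
        raise CalibrationError("standards have identical measured values")
    slope = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / sxx
    return slope, my - slope * mx


def segment_for(
    segments: Sequence[CalibrationSegment], global_position: int
) -> CalibrationSegment:
    """The segment covering a global injection position."""
    for seg in segments:
        if seg.covers(global_position):
            return seg
    raise CalibrationError(f"no calibration segment covers position {global_position}")


def calibrate_delta(raw: float, segment: CalibrationSegment) -> float:
    """Normalize a raw instrument δD (permil) to the VSMOW scale."""
    return segment.intercept + segment.slope * raw


def delta_to_ratio(delta: float, r_vsmow: float = R_VSMOW) -> float:
    """Convert δD (permil, VSMOW) to an absolute D/H ratio.

    ``ratio = R_VSMOW * (1 + delta / 1000)``. δD of −1000‰ or below is
    nonphysical (zero or negative deuterium) and raises ``ValueError``.
    """
    if delta <= -1000.0:
        raise ValueError("delta-D must be > -1000 permil")
    return r_vsmow * (1.0 + delta / 1000.0)


def ratio_to_delta(ratio: float, r_vsmow: float = R_VSMOW) -> float:
    """Inverse of :func:`delta_to_ratio`."""
    if ratio <= 0:
        raise ValueError("D/H ratio must be positive")
    return (ratio / r_vsmow - 1.0) * 1000.0


def summarize_sample(
    sample_id: str,
    retained: Sequence[InjectionRecord],
    segments: Sequence[CalibrationSegment],
    r_vsmow: float = R_VSMOW,
) -> SampleMeasurement:
    """Aggregate one sample's retained injections to a calibrated D/H.

    Each injection is normalized with the segment covering its global
    position, converted to an absolute D/H ratio, then averaged; the SE uses
    the n−1 sample variance (SE = sd/√n). A single retained injection yields
    SE = 0 by convention, with a warning.
    """
    own = [r for r in retained if r.sample_id == sample_id]
    if not own:
        raise QCError([sample_id])
    ratios = [
        delta_to_ratio(calibrate_delta(r.raw_delta_d, segment_for(segments, r.global_position)), r_vsmow)
        for r in own
    ]
    n = len(ratios)
    mean = sum(ratios) / n
    if n == 1:
        warnings.warn(
            f"sample {sample_id!r}: single retained injection, SE set to 0",
            stacklevel=2,
        )
        se = 0.0
    else:
        var = sum((x - mean) ** 2 for x in ratios) / (n - 1)
        se = math.sqrt(var / n)
    return SampleMeasurement(
        sample_id=sample_id,
        mean_delta_d=ratio_to_delta(mean, r_vsmow),
        mean_d_h=mean,
        se_d_h=se,
        n_used=n,
    )


def process_run(
    run: AnalysisRun,
    keep_last: int = 5,
    segment_size: int = 40,
    temp_limit: float = TEMP_CHANGE_LIMIT,
    r_vsmow: float = R_VSMOW,
) -> dict[str, SampleMeasurement]:
    """QC-filter, calibrate and summarize every sample in a run."""
    retained = qc_filter(run, keep_last=keep_last, temp_limit=temp_limit)
    segments = build_calibration_segments(
        run, segment_size=segment_size, keep_last=keep_last, temp_limit=temp_limit
    )
    return {
        sid: summarize_sample(sid, retained, segments, r_vsmow)
        for sid in run.sample_ids
    }
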