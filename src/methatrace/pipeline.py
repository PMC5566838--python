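"""End-to-end composition of the rate calculus, plus YAML configuration.

``run_pipeline`` ties the stages together: raw injections → QC +
segment-wise VSMOW normalization → per-incubation D/H time series →
CH3D activation rates (with killed-control subtraction and replicate
aggregation) → optional 14C oxidation rates → D/14C tracer ratios. Output
is deterministic for a given input set and configuration; a run log
records every QC exclusion and every calibration segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

from . import io as mio
from .chd import (
    DhTimeseries,
    RateEstimate,
    aggregate_replicates,
    rates_from_series,
    subtract_killed_control,
)
from .interpret import exchangeable_hydrogens, tracer_ratio
from .lwia import (
    R_VSMOW,
    build_calibration_segments,
    process_run,
    qc_exclusions,
)
from .radiocarbon import rate_14c
from .simulate import SyntheticExperiment

logger = logging.getLogger("methatrace")


@dataclass
class PipelineConfig:
    """Paths and settings for a full pipeline run.

    Loadable from YAML (JSON is valid YAML) via :meth:`from_file`; defaults
    mirror the measurement protocol: keep the last 5 of 10 injections per
    round, re-calibrate every 40 injections, 0.3 °C/h temperature limit,
    activation stoichiometric factor 4.
    """

    injections: str = ""
    standards: str = ""
    sample_map: str = ""
    incubations: str = ""
    radiocarbon: str = ""  # optional
    dh_series: str = ""  # alternative entry point (already calibrated)
    output_dir: str = "results"
    keep_last: int = 5
    segment_size: int = 40
    temp_limit: float = 0.3
    r_vsmow: float = R_VSMOW
    stoichiometric_factor: float = 4.0
    alpha: float = 1.0
    baseline_mode: Literal["cumulative", "interval"] = "cumulative"
    aliquot_mode: Literal["paper_approximation", "exact_bookkeeping"] = "paper_approximation"
    scaling_factor: float = 1.5
    exchange_model: Literal[
        "activation_stoichiometric", "full_oxidation_complement"
    ] = "full_oxidation_complement"
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)


@dataclass
class PipelineResult:
    """Outputs of a full pipeline run."""

    dh_series: dict[str, DhTimeseries]
    rates_chd: dict[str, list[RateEstimate]]
    rates_chd_corrected: dict[str, list[RateEstimate]]
    rates_14c: dict[str, list[RateEstimate]]
    group_rates: dict[str, RateEstimate]
    tracer_ratios: list[dict]
    qc_log: list[str] = field(default_factory=list)


def calibrate_to_series(
    run,
    sample_map,
    config: PipelineConfig,
    qc_log: list[str] | None = None,
) -> dict[str, DhTimeseries]:
    """Raw run + analyte map → calibrated per-incubation D/H time series."""
    for inj, rule in qc_exclusions(run, config.keep_last, config.temp_limit):
        msg = (
            f"excluded injection pos={inj.global_position} sample={inj.sample_id} "
            f"round={inj.round_index} inj={inj.injection_index}: {rule}"
        )
        logger.debug(msg)
        if qc_log is not None:
            qc_log.append(msg)
    segments = build_calibration_segments(
        run, config.segment_size, config.keep_last, config.temp_limit
    )
    if qc_log is not None:
        for seg in segments:
            qc_log.append(
                f"calibration segment [{seg.start_position}, {seg.end_position}): "
                f"slope={seg.slope:.6g} intercept={seg.intercept:.6g}"
            )
    measurements = process_run(
        run,
        keep_last=config.keep_last,
        segment_size=config.segment_size,
        temp_limit=config.temp_limit,
        r_vsmow=config.r_vsmow,
    )
    by_inc: dict[str, list[tuple[float, float, float]]] = {}
    for sample_id, inc_id, time_h in sample_map:
        m = measurements.get(sample_id)
        if m is None:
            raise KeyError(f"sample {sample_id!r} not present in run")
        by_inc.setdefault(inc_id, []).append((time_h, m.mean_d_h, m.se_d_h))
    return {
        inc_id: DhTimeseries(inc_id, tuple(sorted(points)))
        for inc_id, points in by_inc.items()
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full calculus and write results to ``config.output_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    qc_log: list[str] = []

    incubations = mio.read_incubations(config.incubations)

    if config.dh_series:
        series = mio.read_dh_series(config.dh_series)
    else:
        run = mio.read_injections(config.injections)
        run.standards = mio.read_standards(config.standards)
        sample_map = mio.read_sample_map(config.sample_map)
        series = calibrate_to_series(run, sample_map, config, qc_log)

    rates_chd: dict[str, list[RateEstimate]] = {}
    for inc_id, ts in series.items():
        spec = incubations.get(inc_id)
        if spec is None:
            raise KeyError(f"incubation {inc_id!r} missing from metadata")
        rates_chd[inc_id] = rates_from_series(
            ts,
            spec,
            stoichiometric_factor=config.stoichiometric_factor,
            alpha=config.alpha,
            baseline=config.baseline_mode,
            aliquot_mode=config.aliquot_mode,
        )

    rates_corrected = _subtract_controls(rates_chd, incubations)
    group_rates = _aggregate_groups(rates_corrected, incubations)

    rates_14c: dict[str, list[RateEstimate]] = {}
    if config.radiocarbon:
        for m, inv in mio.read_radiocarbon(config.radiocarbon):
            rates_14c.setdefault(m.incubation_id, []).append(rate_14c(m, inv))

    ratios = _tracer_ratios(group_rates, rates_14c, incubations, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_dh_series(series.values(), out / "dh_series.csv")
    combined = {k: list(v) for k, v in rates_corrected.items()}
    for k, v in rates_14c.items():
        combined.setdefault(k, []).extend(v)
    mio.write_rates(combined, out / "rates.csv")
    mio.write_tracer_ratios(ratios, out / "tracer_ratios.csv")
    (out / "run_log.txt").write_text("\n".join(qc_log) + "\n")

    return PipelineResult(
        dh_series=series,
        rates_chd=rates_chd,
        rates_chd_corrected=rates_corrected,
        rates_14c=rates_14c,
        group_rates=group_rates,
        tracer_ratios=ratios,
        qc_log=qc_log,
    )


def _subtract_controls(rates, incubations):
    """Subtract mean killed-control rates (matched by interval) everywhere."""
    killed_by_interval: dict[tuple[float, float], list[RateEstimate]] = {}
    for inc_id, estimates in rates.items():
        spec = incubations.get(inc_id)
        if spec is not None and spec.is_killed_control:
            for e in estimates:
                killed_by_interval.setdefault(e.interval, []).append(e)
    if not killed_by_interval:
        return {k: list(v) for k, v in rates.items()}
    out = {}
    for inc_id, estimates in rates.items():
        spec = incubations.get(inc_id)
        if spec is not None and spec.is_killed_control:
            out[inc_id] = list(estimates)
            continue
        corrected = []
        for e in estimates:
            killed = killed_by_interval.get(e.interval)
            corrected.append(subtract_killed_control(e, killed) if killed else e)
        out[inc_id] = corrected
    return out


def _aggregate_groups(rates, incubations):
    """Aggregate final-interval rates across biological replicates."""
    groups: dict[str, list[RateEstimate]] = {}
    for inc_id, estimates in rates.items():
        spec = incubations.get(inc_id)
        if spec is None or spec.is_killed_control or not estimates:
            continue
        key = spec.replicate_group or inc_id
        groups.setdefault(key, []).append(estimates[-1])
    return {g: aggregate_replicates(es) for g, es in groups.items()}


def _tracer_ratios(group_rates, rates_14c, incubations, config):
    """D/14C tracer ratios per replicate group where both tracers exist."""
    c14_by_group: dict[str, list[RateEstimate]] = {}
    for inc_id, estimates in rates_14c.items():
        spec = incubations.get(inc_id)
        if spec is None or spec.is_killed_control:
            continue
        key = (spec.replicate_group or inc_id) if spec else inc_id
        c14_by_group.setdefault(key, []).extend(estimates)
    rows = []
    for group, chd_est in group_rates.items():
        c14_list = c14_by_group.get(group)
        if not c14_list:
            continue
        c14_mean = sum(e.value for e in c14_list) / len(c14_list)
        if c14_mean <= 0 or chd_est.value <= 0:
            # a nonpositive noisy rate admits no meaningful ratio
            continue
        res = tracer_ratio(chd_est.value, c14_mean, se_chd=chd_est.se)
        row = {
            "group": group,
            "phase": res.phase_or_condition,
            "ratio": res.ratio,
            "se": res.se,
            "n_exchange_modelA": None,
            "n_exchange_modelB": None,
        }
        if res.ratio > 0:
            row["n_exchange_modelA"] = exchangeable_hydrogens(
                min(res.ratio, 4.0), "activation_stoichiometric"
            ).n_exchange
            if res.ratio >= 1:
                row["n_exchange_modelB"] = exchangeable_hydrogens(
                    res.ratio, "full_oxidation_complement"
                ).n_exchange
        rows.append(row)
    return rows


def analyze_experiment(
    exp: SyntheticExperiment,
    stoichiometric_factor: float = 4.0,
    baseline: Literal["cumulative", "interval"] = "cumulative",
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the analysis side of the calculus on a simulated experiment.

    Processes the simulated raw injection run through QC, calibration and
    the rate equations, subtracts the killed-control twin, and computes
    14C rates and the tracer ratio — entirely in memory.
    """
    if config is None:
        config = PipelineConfig()
    config.stoichiometric_factor = stoichiometric_factor
    config.baseline_mode = baseline

    qc_log: list[str] = []
    series = calibrate_to_series(exp.run, exp.sample_map, config, qc_log)

    incubations = exp.incubations
    rates_chd = {
        inc_id: rates_from_series(
            ts,
            incubations[inc_id],
            stoichiometric_factor=stoichiometric_factor,
            alpha=config.alpha,
            baseline=baseline,
        )
        for inc_id, ts in series.items()
    }
    rates_corrected = _subtract_controls(rates_chd, incubations)
    group_rates = _aggregate_groups(rates_corrected, incubations)

    from .radiocarbon import Ch4Inventory

    inv = Ch4Inventory(exp.config.initial_ch4_mol, "declared")
    rates_14c: dict[str, list[RateEstimate]] = {}
    for m in exp.radiocarbon:
        rates_14c.setdefault(m.incubation_id, []).append(rate_14c(m, inv))

    ratios = _tracer_ratios(group_rates, rates_14c, incubations, config)
    return PipelineResult(
        dh_series=series,
        rates_chd=rates_chd,
        rates_chd_corrected=rates_corrected,
        rates_14c=rates_14c,
        group_rates=group_rates,
        tracer_ratios=ratios,
        qc_log=qc_log,
    )
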