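"""CSV readers and writers for the pipeline's external interfaces.

All files are comma-separated UTF-8 with dot decimals; scientific notation
is accepted on read. Column schemas are validated up front and schema
violations name the missing column; unparseable rows are reported with
their row number.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chd import DhTimeseries, IncubationSpec, RateEstimate
from .errors import SchemaError
from .lwia import AnalysisRun, InjectionRecord, IsotopeStandard
from .radiocarbon import Ch4Inventory, RadiocarbonMeasurement

INJECTION_COLUMNS = ["sample_id", "round", "injection", "raw_delta_d"]
INJECTION_DIAGNOSTIC_COLUMNS = ["temp_change_rate", "pressure_rising", "position"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_injections(path: str | Path) -> AnalysisRun:
    """Read per-injection LWIA data.

    Schema: ``sample_id,round,injection,raw_delta_d`` plus optional
    diagnostic columns ``temp_change_rate,pressure_rising,position``.
    Missing diagnostics are treated as passing (with a warning); a missing
    ``position`` column is filled from row order.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, INJECTION_COLUMNS, path)
    absent = [c for c in ("temp_change_rate", "pressure_rising") if c not in df.columns]
    if absent:
        warnings.warn(
            f"{path}: diagnostic column(s) {', '.join(absent)} absent; "
            "treating all injections as passing diagnostics",
            stacklevel=2,
        )
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            records.append(
                InjectionRecord(
                    sample_id=str(row.sample_id),
                    round_index=int(row.round),
                    injection_index=int(row.injection),
                    raw_delta_d=float(row.raw_delta_d),
                    temp_change_rate=(
                        float(row.temp_change_rate)
                        if "temp_change_rate" in df.columns
                        and pd.notna(row.temp_change_rate)
                        else None
                    ),
                    pressure_rising=(
                        bool(row.pressure_rising)
                        if "pressure_rising" in df.columns
                        and pd.notna(row.pressure_rising)
                        else None
                    ),
                    global_position=(
                        int(row.position) if "position" in df.columns else idx - 1
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: unparseable row at line {idx}: {exc}") from exc
    return AnalysisRun(injections=records)


def read_standards(path: str | Path) -> dict[str, IsotopeStandard]:
    """Read standards: ``standard_id,known_delta_d_permil``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["standard_id", "known_delta_d_permil"], path)
    return {
        str(r.standard_id): IsotopeStandard(str(r.standard_id), float(r.known_delta_d_permil))
        for r in df.itertuples(index=False)
    }


def read_incubations(path: str | Path) -> dict[str, IncubationSpec]:
    """Read incubation metadata:
    ``incubation_id,water_volume_l,inoculum_volume_cm3,f_ch3d,is_killed_control,replicate_group``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["incubation_id", "water_volume_l", "inoculum_volume_cm3", "f_ch3d"],
        path,
    )
    out = {}
    for idx, r in enumerate(df.itertuples(index=False), start=2):
        try:
            out[str(r.incubation_id)] = IncubationSpec(
                incubation_id=str(r.incubation_id),
                water_volume=float(r.water_volume_l),
                inoculum_volume=float(r.inoculum_volume_cm3),
                f_ch3d=float(r.f_ch3d),
                is_killed_control=bool(getattr(r, "is_killed_control", False)),
                replicate_group=str(getattr(r, "replicate_group", "")),
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: unparseable row at line {idx}: {exc}") from exc
    return out


def read_sample_map(path: str | Path) -> list[tuple[str, str, float]]:
    """Read the analyte → incubation/time map: ``sample_id,incubation_id,time_h``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "incubation_id", "time_h"], path)
    return [
        (str(r.sample_id), str(r.incubation_id), float(r.time_h))
        for r in df.itertuples(index=False)
    ]


def read_dh_series(path: str | Path) -> dict[str, DhTimeseries]:
    """Read calibrated D/H series: ``incubation_id,time_h,d_h,se``."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["incubation_id", "time_h", "d_h"], path)
    if "se" not in df.columns:
        df = df.assign(se=0.0)
    out = {}
    for inc_id, grp in df.groupby("incubation_id", sort=False):
        grp = grp.sort_values("time_h")
        out[str(inc_id)] = DhTimeseries(
            incubation_id=str(inc_id),
            points=tuple(
                (float(t), float(r), float(s))
                for t, r, s in zip(grp.time_h, grp.d_h, grp.se)
            ),
        )
    return out


def write_dh_series(series: Iterable[DhTimeseries], path: str | Path) -> None:
    rows = [
        {"incubation_id": s.incubation_id, "time_h": t, "d_h": r, "se": se}
        for s in series
        for t, r, se in s.points
    ]
    pd.DataFrame(rows, columns=["incubation_id", "time_h", "d_h", "se"]).to_csv(
        path, index=False
    )


def read_radiocarbon(
    path: str | Path,
) -> list[tuple[RadiocarbonMeasurement, Ch4Inventory]]:
    """Read 14C data: ``incubation_id,activity_14co2_bq,activity_14ch4_vial1_bq,
    activity_14ch4_vial2_bq,time_d,inoculum_volume_cm3,total_ch4_mol``.

    The two combustion vials are summed on read (provenance preserved in
    the file).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df,
        [
            "incubation_id",
            "activity_14co2_bq",
            "activity_14ch4_vial1_bq",
            "activity_14ch4_vial2_bq",
            "time_d",
            "inoculum_volume_cm3",
            "total_ch4_mol",
        ],
        path,
    )
    out = []
    for idx, r in enumerate(df.itertuples(index=False), start=2):
        try:
            m = RadiocarbonMeasurement(
                incubation_id=str(r.incubation_id),
                activity_14co2=float(r.activity_14co2_bq),
                activity_14ch4=float(r.activity_14ch4_vial1_bq)
                + float(r.activity_14ch4_vial2_bq),
                incubation_time=float(r.time_d),
                inoculum_volume=float(r.inoculum_volume_cm3),
            )
            out.append((m, Ch4Inventory(float(r.total_ch4_mol), "declared")))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: unparseable row at line {idx}: {exc}") from exc
    return out


def write_injections(run: AnalysisRun, path: str | Path) -> None:
    """Write a run back to the injection CSV schema."""
    rows = [
        {
            "sample_id": i.sample_id,
            "round": i.round_index,
            "injection": i.injection_index,
            "raw_delta_d": i.raw_delta_d,
            "temp_change_rate": i.temp_change_rate,
            "pressure_rising": i.pressure_rising,
            "position": i.global_position,
        }
        for i in run.injections
    ]
    cols = [
        "sample_id", "round", "injection", "raw_delta_d",
        "temp_change_rate", "pressure_rising", "position",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_standards(standards: dict[str, IsotopeStandard], path: str | Path) -> None:
    rows = [
        {"standard_id": s.standard_id, "known_delta_d_permil": s.known_delta_d}
        for s in standards.values()
    ]
    pd.DataFrame(rows, columns=["standard_id", "known_delta_d_permil"]).to_csv(
        path, index=False
    )


def write_incubations(specs: Iterable[IncubationSpec], path: str | Path) -> None:
    rows = [
        {
            "incubation_id": s.incubation_id,
            "water_volume_l": s.water_volume,
            "inoculum_volume_cm3": s.inoculum_volume,
            "f_ch3d": s.f_ch3d,
            "is_killed_control": s.is_killed_control,
            "replicate_group": s.replicate_group,
        }
        for s in specs
    ]
    cols = [
        "incubation_id", "water_volume_l", "inoculum_volume_cm3", "f_ch3d",
        "is_killed_control", "replicate_group",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_sample_map(sample_map: Sequence[tuple[str, str, float]], path: str | Path) -> None:
    pd.DataFrame(sample_map, columns=["sample_id", "incubation_id", "time_h"]).to_csv(
        path, index=False
    )


def write_radiocarbon(
    rows: Sequence[tuple[RadiocarbonMeasurement, Ch4Inventory]], path: str | Path
) -> None:
    recs = [
        {
            "incubation_id": m.incubation_id,
            "activity_14co2_bq": m.activity_14co2,
            # the simulator produces a single combusted total; split evenly
            "activity_14ch4_vial1_bq": m.activity_14ch4 / 2.0,
            "activity_14ch4_vial2_bq": m.activity_14ch4 / 2.0,
            "time_d": m.incubation_time,
            "inoculum_volume_cm3": m.inoculum_volume,
            "total_ch4_mol": inv.total_ch4,
        }
        for m, inv in rows
    ]
    cols = [
        "incubation_id", "activity_14co2_bq", "activity_14ch4_vial1_bq",
        "activity_14ch4_vial2_bq", "time_d", "inoculum_volume_cm3", "total_ch4_mol",
    ]
    pd.DataFrame(recs, columns=cols).to_csv(path, index=False)


def write_rates(rates: dict[str, Sequence[RateEstimate]], path: str | Path) -> None:
    """Write rates: ``incubation_id,t_start_h,t_end_h,rate_nmol_cm3_d,se,cumulative_nmol,method``."""
    rows = [
        {
            "incubation_id": inc_id,
            "t_start_h": e.interval[0],
            "t_end_h": e.interval[1],
            "rate_nmol_cm3_d": e.value,
            "se": e.se,
            "cumulative_nmol": e.cumulative_nmol,
            "method": e.method,
        }
        for inc_id, estimates in rates.items()
        for e in estimates
    ]
    cols = [
        "incubation_id", "t_start_h", "t_end_h", "rate_nmol_cm3_d", "se",
        "cumulative_nmol", "method",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_tracer_ratios(rows: Sequence[dict], path: str | Path) -> None:
    """Write ratios: ``group,phase,ratio,se,n_exchange_modelA,n_exchange_modelB``."""
    cols = ["group", "phase", "ratio", "se", "n_exchange_modelA", "n_exchange_modelB"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
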