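import pytest

from methatrace import AnalysisRun, InjectionRecord, IsotopeStandard


def make_round(sample_id, round_index, values, start_pos, temp=0.0, pressure=False):
    """Build one round of injections with consecutive global positions."""
    return [
        InjectionRecord(
            sample_id=sample_id,
            round_index=round_index,
            injection_index=i + 1,
            raw_delta_d=v,
            temp_change_rate=temp,
            pressure_rising=pressure,
            global_position=start_pos + i,
        )
        for i, v in enumerate(values)
    ]


def make_simple_run(sample_values, std_values=((2.0, 0.5), (-70.0, -73.4)), rounds=4):
    """A run: one round per standard, then `rounds` rounds of 10 per sample.

    ``sample_values`` maps sample_id -> constant raw delta; ``std_values``
    gives (measured, known) per standard. Returns run with a single
    calibration segment when segment_size >= total size.
    """
    injections = []
    standards = {}
    pos = 1
    for k, (measured, known) in enumerate(std_values, start=1):
        sid = f"std{k}"
        standards[sid] = IsotopeStandard(sid, known)
        injections += make_round(sid, 1, [measured] * 10, pos)
        pos += 10
    for sid, raw in sample_values.items():
        for r in range(1, rounds + 1):
            injections += make_round(sid, r, [raw] * 10, pos)
            pos += 10
    return AnalysisRun(injections=injections, standards=standards)


@pytest.fixture
def identity_run():
    """Run whose standards are measured exactly at their known values."""
    return make_simple_run(
        {"s1": -34.0},
        std_values=((0.5, 0.5), (-73.4, -73.4)),
    )
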