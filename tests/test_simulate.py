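"""Forward simulator: truth construction, instrument model, oracles."""

import math

import numpy as np
import pytest

from methatrace import (
    ConsumptionModel,
    InstrumentModel,
    SimulationConfig,
    analyze_experiment,
    dnew_molecular_oracle,
    hydrogen_inventory,
    process_run,
    rate_14c,
    simulate_consumption,
    simulate_experiment,
    simulate_injection_run,
    simulate_radiocarbon,
    simulate_water_dh,
)
from methatrace.radiocarbon import Ch4Inventory

QUIET = InstrumentModel(injection_sd=0.0, memory_coeff=0.0, drift_per_injection=0.0)


def quiet_config(rate=100.0, n_exchange=2.0, phi=1.0, **kw):
    return SimulationConfig(
        consumption=ConsumptionModel(rate=rate),
        n_exchange_true=n_exchange,
        phi=phi,
        instrument=QUIET,
        counting_cv=0.0,
        seed=1,
        **kw,
    )


class TestConsumption:
    def test_dead_culture_consumes_nothing(self):
        cfg = quiet_config(rate=0.0)
        assert np.all(simulate_consumption(cfg, [0, 24, 48]) == 0.0)

    def test_linear_model_arithmetic(self):
        cfg = quiet_config(rate=100.0)  # inoculum 10 cm^3
        consumed = simulate_consumption(cfg, [0.0, 48.0])
        assert consumed[-1] == pytest.approx(2000.0)

    def test_logistic_saturates_at_max_minus_offset(self):
        cfg = SimulationConfig(
            consumption=ConsumptionModel(
                kind="logistic", max_nmol=5000.0, steepness=0.1, midpoint_h=50.0
            ),
            instrument=QUIET,
            counting_cv=0.0,
        )
        consumed = simulate_consumption(cfg, [0.0, 1e4])
        offset = 5000.0 / (1 + math.exp(0.1 * 50.0))
        assert consumed[0] == 0.0
        assert consumed[-1] == pytest.approx(5000.0 - offset, rel=1e-6)

    def test_consumption_is_deterministic(self):
        cfg = quiet_config()
        a = simulate_consumption(cfg, [0, 10, 20])
        b = simulate_consumption(cfg, [0, 10, 20])
        assert np.array_equal(a, b)


class TestWaterDh:
    def test_zero_consumption_keeps_baseline(self):
        cfg = quiet_config()
        dh = simulate_water_dh([0.0, 0.0, 0.0], cfg)
        assert np.all(dh == cfg.baseline_dh)

    def test_expectation_formula(self):
        cfg = quiet_config(n_exchange=2.0)
        dh = simulate_water_dh([0.0, 1000.0], cfg)
        expected = cfg.baseline_dh + (
            1000.0 * 1e-9 * 0.5 * 0.5 / hydrogen_inventory(cfg.incubation)
        )
        assert dh[-1] == pytest.approx(expected, rel=1e-12)

    def test_decreasing_consumption_rejected(self):
        with pytest.raises(ValueError):
            simulate_water_dh([0.0, 10.0, 5.0], quiet_config())


class TestMolecularOracle:
    @pytest.mark.parametrize("f,n", [(1.0, 4.0), (0.5, 2.0), (0.5, 1.0)])
    def test_agrees_with_analytic_expectation_within_3_sigma(self, f, n):
        n_mol = 10**6
        p = f * n / 4.0
        sigma = math.sqrt(p * (1 - p) / n_mol)
        observed = dnew_molecular_oracle(n_mol, f, n, seed=42)
        assert abs(observed - p) <= 3 * sigma  # sigma = 0 at p = 1 is exact

    def test_pipeline_expectation_matches_oracle(self):
        # analytic D_new per activated mole vs molecule-level simulation
        cfg = quiet_config(n_exchange=2.0)
        consumed_nmol = 1000.0
        dh = simulate_water_dh([0.0, consumed_nmol], cfg)
        d_per_molecule = (
            (dh[-1] - cfg.baseline_dh)
            * hydrogen_inventory(cfg.incubation)
            / (consumed_nmol * 1e-9)
        )
        n_mol = 10**6
        p = cfg.incubation.f_ch3d * cfg.n_exchange_true / 4.0
        sigma = math.sqrt(p * (1 - p) / n_mol)
        oracle = dnew_molecular_oracle(
            n_mol, cfg.incubation.f_ch3d, cfg.n_exchange_true, seed=7
        )
        assert abs(d_per_molecule - oracle) < 3 * sigma


class TestInjectionRun:
    def test_noise_free_retained_means_equal_truth(self):
        cfg = quiet_config()
        dh_true = 1.43e-4
        run = simulate_injection_run([("s", dh_true)], cfg)
        measurements = process_run(run, segment_size=40)
        assert measurements["s"].mean_d_h == pytest.approx(dh_true, rel=1e-12)
        assert measurements["s"].se_d_h == pytest.approx(0.0, abs=1e-18)

    def test_fixed_seed_reproduces_run(self):
        cfg = SimulationConfig(seed=5)
        a = simulate_injection_run([("s", 1.43e-4)], cfg)
        b = simulate_injection_run([("s", 1.43e-4)], cfg)
        assert [i.raw_delta_d for i in a.injections] == [
            i.raw_delta_d for i in b.injections
        ]

    def test_different_seeds_differ_in_noise(self):
        a = simulate_injection_run([("s", 1.43e-4)], SimulationConfig(seed=1))
        b = simulate_injection_run([("s", 1.43e-4)], SimulationConfig(seed=2))
        assert [i.raw_delta_d for i in a.injections] != [
            i.raw_delta_d for i in b.injections
        ]

    def test_memory_biases_early_injections_and_last_five_remedy(self):
        inst = InstrumentModel(
            injection_sd=0.0, memory_coeff=0.3, memory_decay=0.5,
            drift_per_injection=0.0,
        )
        cfg = SimulationConfig(instrument=inst, counting_cv=0.0, seed=0)
        dh_true = 1.50e-4  # far from the standards' values
        run = simulate_injection_run([("s", dh_true)], cfg)
        measurements = process_run(run, segment_size=40)
        # first sample round follows std2; carry-over on retained injections
        # is bounded by memory_coeff * decay^5 of the analyte gap (~1%)
        rel_err = abs(measurements["s"].mean_d_h - dh_true) / dh_true
        assert rel_err < 0.01
        # whereas the first injection of the first sample round is visibly
        # pulled toward the previous analyte
        first = next(
            i for i in run.injections
            if i.sample_id == "s" and i.round_index == 1 and i.injection_index == 1
        )
        last = next(
            i for i in run.injections
            if i.sample_id == "s" and i.round_index == 1 and i.injection_index == 10
        )
        assert abs(first.raw_delta_d - last.raw_delta_d) > 1.0  # permil


class TestRadiocarbonSimulation:
    def test_full_oxidation_round_trip(self):
        cfg = quiet_config(rate=100.0, phi=1.0)
        consumed = simulate_consumption(cfg, cfg.sampling_times_h)
        ms = simulate_radiocarbon(consumed, cfg.sampling_times_h, cfg)
        inv = Ch4Inventory(cfg.initial_ch4_mol)
        for m in ms:
            assert rate_14c(m, inv).value == pytest.approx(100.0, rel=1e-9)

    def test_no_full_oxidation_gives_zero(self):
        cfg = quiet_config(phi=0.0)
        consumed = simulate_consumption(cfg, cfg.sampling_times_h)
        ms = simulate_radiocarbon(consumed, cfg.sampling_times_h, cfg)
        inv = Ch4Inventory(cfg.initial_ch4_mol)
        assert all(rate_14c(m, inv).value == 0.0 for m in ms)


class TestExperimentBundle:
    @pytest.mark.parametrize("n_exchange", [1.0, 2.0, 4.0])
    def test_noise_free_round_trip_with_matched_stoichiometry(self, n_exchange):
        # the analysis recovers the configured rate exactly when its
        # stoichiometric factor matches 4 / n_exchange
        cfg = quiet_config(rate=250.0, n_exchange=n_exchange)
        exp = simulate_experiment(cfg)
        res = analyze_experiment(exp, stoichiometric_factor=4.0 / n_exchange)
        assert res.group_rates["sim"].value == pytest.approx(250.0, rel=1e-9)

    def test_default_factor_reports_activation_end_member(self):
        # at the protocol's factor 4 the estimate is rate x n_exchange
        cfg = quiet_config(rate=100.0, n_exchange=2.0)
        exp = simulate_experiment(cfg)
        res = analyze_experiment(exp, stoichiometric_factor=4.0)
        assert res.group_rates["sim"].value == pytest.approx(200.0, rel=1e-9)
        assert exp.expected_rchd == pytest.approx(200.0)

    def test_tracer_ratio_converges_to_n_over_phi(self):
        cfg = quiet_config(rate=100.0, n_exchange=2.0, phi=0.5)
        exp = simulate_experiment(cfg)
        res = analyze_experiment(exp)
        (row,) = [r for r in res.tracer_ratios if r["group"] == "sim"]
        assert row["ratio"] == pytest.approx(2.0 / 0.5, rel=1e-9)

    def test_two_seeds_share_truth_but_not_noise(self):
        a = simulate_experiment(SimulationConfig(seed=1))
        b = simulate_experiment(SimulationConfig(seed=2))
        assert np.array_equal(a.true_consumed_nmol, b.true_consumed_nmol)
        assert np.array_equal(a.true_dh, b.true_dh)
        assert [i.raw_delta_d for i in a.run.injections] != [
            i.raw_delta_d for i in b.run.injections
        ]

    def test_killed_twin_has_zero_consumption_truth(self):
        exp = simulate_experiment(SimulationConfig(seed=3))
        assert len(exp.killed_ids) == exp.config.n_replicates
        assert all(exp.incubations[k].is_killed_control for k in exp.killed_ids)
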