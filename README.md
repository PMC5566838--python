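# methatrace

Rate calculus for dual-tracer methane metabolism measurements: turns raw
liquid-water isotope analyzer (LWIA) δD injections and ¹⁴C activity
partitions into methane activation and full-oxidation rates, tracer
ratios, and their physiological interpretations.

The measurement idea: incubations receive monodeuterated methane (CH₃D).
When an organism activates a CH₃D molecule, its deuterium can end up in
the surrounding water, so the aqueous D/H ratio climbs in proportion to
cumulative methane activation. A parallel ¹⁴CH₄ radiotracer treatment
measures complete oxidation to CO₂. The ratio of the two rates (the
D/¹⁴C tracer ratio) constrains how many of methane's four hydrogen atoms
reach water-exchangeable products in a given metabolism.

## Quick start (library)

```python
from methatrace import (
    DhTimeseries, IncubationSpec, rates_from_series, tracer_ratio,
    exchangeable_hydrogens,
)

spec = IncubationSpec(
    incubation_id="culture", water_volume=0.00944,  # litres
    inoculum_volume=10.0,                           # cm^3
    f_ch3d=0.5,                                     # CH3D fraction of headspace methane
)
series = DhTimeseries("culture", (
    (0.0, 1.40e-4, 3.1e-8),     # (time_h, D/H, SE)
    (47.5, 1.45e-4, 3.0e-8),
))
est = rates_from_series(series, spec)[0]
print(est.value, "nmol cm^-3 d^-1")

ratio = tracer_ratio(4.16e4, 2.78e4, chd_time=47.5, c14_time=47.5)
print(ratio.rounded)                                         # 1.5
print(exchangeable_hydrogens(ratio.rounded, "full_oxidation_complement"))
```

## Quick start (CLI)

```bash
# simulate a full dual-tracer experiment with known truth
methatrace simulate --seed 1 --rate 100 --out demo/

# run the whole pipeline from a YAML config
cat > demo/config.yaml <<EOF
injections: demo/injections.csv
standards: demo/standards.csv
sample_map: demo/sample_map.csv
incubations: demo/incubations.csv
radiocarbon: demo/radiocarbon.csv
output_dir: demo/results
EOF
methatrace run --config demo/config.yaml
```

Other subcommands: `calibrate`, `rates-chd`, `rates-14c`,
`tracer-ratio`, `backflux`, `solubility`. Each is a thin wrapper over
the library API.

## Modules

| Module | What it does |
| --- | --- |
| `methatrace.lwia` | Injection QC (last-5-of-10 memory remedy, temperature/pressure diagnostics) and segment-wise two-point VSMOW calibration |
| `methatrace.chd` | CH₃D activation-rate calculus: hydrogen inventory, new deuterium, 1:3 D:H stoichiometry, headspace correction, volumetric rates, killed-control subtraction, replicate aggregation |
| `methatrace.radiocarbon` | ¹⁴CH₄ full-oxidation rates from label partitions, GC quantification, headspace inventories |
| `methatrace.interpret` | D/¹⁴C tracer ratio, exchangeable-hydrogen models, back-flux bounds, precision comparison |
| `methatrace.solubility` | Henry's-law dissolved methane with van 't Hoff and Setschenow adjustments |
| `methatrace.simulate` | Forward simulator (truth → raw observables) with a per-molecule Monte Carlo oracle |
| `methatrace.io`, `methatrace.pipeline`, `methatrace.cli` | CSV schemas, YAML config, end-to-end pipeline, command line |

The full derivation of each equation is in [docs/methods.md](docs/methods.md).
Narrative walkthroughs live in [examples/](examples/).

## Testing

```bash
python -m pytest -q
```

The suite mixes worked-example unit tests, hypothesis property tests,
and acceptance tests (`tests/test_acceptance.py`) that pin published
reference values. `scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the headline acceptance target.
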