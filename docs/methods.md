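# Methods

This document derives every equation the package implements, in the
order the pipeline applies them, and records the modelling choices that
are not visible from the code alone.

## 1. LWIA acquisition and quality control (`methatrace.lwia`)

Each analyte (a water subsample from one incubation at one time point)
is measured in 4 rounds of 10 injections on a liquid water isotope
analyzer. Two remedies for instrument artifacts are applied before any
statistics:

1. **Memory**: early injections of a round carry over part of the
   previous analyte. Only the **last 5 injections of each round** are
   retained (20 of 40 per analyte). With a geometric carry-over
   `m_i = m₀ · λ^(i−1)`, retaining injections 6–10 bounds the residual
   carry-over by `m₀ λ⁵` (≈1 % at m₀ = 0.3, λ = 0.5).
2. **Diagnostics**: injections acquired while the cavity temperature
   changed faster than 0.3 °C h⁻¹, or while cavity pressure was rising,
   are excluded. Every exclusion is logged once with its triggering rule.

**Calibration** is a two-point affine normalization to the VSMOW scale,
re-anchored every 40 injections: within each ≤40-injection segment the
retained means of two standard waters define slope and intercept
(ordinary least squares if more than two standards are present). By
construction the calibrated standard means reproduce their assigned
values exactly. δD converts to an absolute ratio via

```
D/H = R_VSMOW · (1 + δD/1000),   R_VSMOW = 155.76 × 10⁻⁶
```

Per-analyte summaries are the mean and standard error (n−1 convention)
of the retained, calibrated injections.

## 2. CH₃D activation rates (`methatrace.chd`)

Given a calibrated aqueous D/H time series for one incubation:

1. **Hydrogen inventory** (Eq. 1): `H = V_water × 55.5 mol L⁻¹ × 2 =
   V_water × 111 mol L⁻¹` — moles of H atoms in the aqueous phase.
2. **New deuterium** (Eq. 2): `D_new = [(D/H)_t − (D/H)_0] × H`.
   Because D is trace-level, the denominator H is effectively constant.
3. **Stoichiometry** (Eq. 5): each CH₃D carries one D among four H
   positions. If only one methane-derived H reaches water per activated
   molecule, the activated methane is `C = 4 × D_new` (the default
   stoichiometric factor of 4; see §6 for other assumptions).
4. **Tracer-fraction correction** (Eq. 6): only a fraction `f_CH₃D` of
   the headspace methane is labelled, so total methane activated is
   `C_corr = C / f_CH₃D`.
5. **Volumetric rate** (Eq. 7):
   `R_CH₃D = C_corr × 10⁹ / (t_days × V_inoculum)` in nmol cm⁻³ d⁻¹.
   Input times are hours; the conversion to days happens here only.

**Aliquot bookkeeping.** Removing a fluid aliquot for analysis and
replacing it with unlabelled water removes deuterium. The default
(`paper_approximation`) ignores this, as the original protocol does; the
`exact_bookkeeping` mode credits each aliquot with
`(D/H_aliquot − D/H_baseline) × V_aliquot × 111` moles of D. For a 1 ml
aliquot at D/H 1.45×10⁻⁴ against a 1.40×10⁻⁴ baseline this is
5.55×10⁻⁷ mol — small but not zero.

**Controls and replicates.** The mean killed-control rate (matched by
time interval) is subtracted from live rates; SEs combine in quadrature.
Negative corrected rates are reported as-is (clamping would bias
aggregation). Biological replicates aggregate as mean ± sd/√n.

## 3. ¹⁴C full-oxidation rates (`methatrace.radiocarbon`)

A trace of ¹⁴CH₄ is added; after incubation the label is partitioned
into residual ¹⁴CH₄ and produced ¹⁴CO₂ (+ acid-labile carbonates). The
oxidized fraction times the (unlabelled) methane inventory gives the
oxidized amount (Eq. 8):

```
R_14C = [¹⁴CO₂ / (¹⁴CH₄ + ¹⁴CO₂)] × CH₄_initial / (V_inoculum × t_days)
```

Because only the activity *ratio* enters, the result is invariant to
the label's specific activity. Supporting utilities: GC response →
concentration inversion (linear two-anchor calibration, warning on
extrapolation), ideal-gas headspace inventories (`n = pV/RT`), optional
recovery-efficiency adjustment (disabled by default), optional blank
fraction subtraction.

## 4. The D/¹⁴C tracer ratio (`methatrace.interpret`)

`tracer_ratio(chd, c14)` divides the two rates; amounts with separate
sampling times are converted to rates first. The SE uses the first-order
(delta-method) propagation
`SE = |ratio| × √((SE_chd/chd)² + (SE_c14/c14)²)`.

Two limiting readings convert a ratio into `n`, the average number of
methane-derived H atoms entering water-exchangeable products per fully
oxidized methane:

- **`activation_stoichiometric`**: activation and full oxidation are
  the same flux, so `n = ratio` directly (capped at 4, with a warning,
  since methane has only four hydrogens).
- **`full_oxidation_complement`**: the CH₃D signal scales with `n/4` of
  the full-oxidation flux, so `n = 4 / ratio` (requires ratio ≥ 1).

The two models coincide only at `n = 2`.

## 5. Back-flux bounds (`methatrace.interpret.backflux_bounds`)

Reverse operation of the methane-activating enzyme re-forms CH₄ (and
CH₃D → CH₄ isotopologue exchange inflates D/H without net oxidation).
From headspace CH₄ percentages at the start and end of an incubation and
the ¹⁴C-measured fully-oxidized percentage:

- Mcr-only (no net oxidation): `4 × ΔCH₄%` (the factor 4 restores the
  1-in-4 chance that back-flux returns the D).
- Envelope accounting for net oxidation: lower bound
  `ΔCH₄% × (1 − oxidized/100)`, upper bound `4 ×` lower. The 4× relation
  is enforced structurally.

## 6. The stoichiometric factor and the simulator's round trip

The generator releases, per activated methane,
`f_CH₃D × (n_true/4) × α` deuterium atoms into water (α an optional
fractionation multiplier). Pushing that through Eqs. 2–7 with analysis
factor `s` yields

```
estimate = true rate × n_true × α × (s/4)
```

so exact recovery requires `s = 4/n_true`; the default `s = 4` is the
conservative one-H end member and reports `rate × n_true` when more
hydrogens exchange. The tracer ratio of the pipeline outputs at `s = 4`
converges to `n_true/φ` (φ = fraction of activated methane carried to
full oxidation) as noise → 0, which is exactly the quantity §4
interprets. Tests assert both identities.

## 7. Solubility (`methatrace.solubility`)

Henry's law, `c = k_H × p`, with `k_H` in mol m⁻³ Pa⁻¹ so that the
result is mol m⁻³ = mM. Temperature adjustment is van 't Hoff,
`k = k_ref · exp(B(1/T − 1/T_ref))` with B ≈ 1700 K for methane;
salinity uses the Setschenow relation `k → k · 10^(−K_s · S)`.

## 8. Forward simulator (`methatrace.simulate`)

Truth → observables, so every stage is testable without real data:

- consumption: linear (constant rate) or logistic (growth-curve-like);
- aqueous D/H: expectation model (mole quantities ≈ 10¹⁹ molecules make
  binomial spread negligible); a per-molecule Bernoulli sampler exists
  separately as an independent Monte Carlo oracle for tests;
- LWIA run: per-analyte blocks of standard–standard–4 sample
  rounds–standard–standard (80 injections) so every 40-injection
  calibration segment contains both standards; distortions are an
  instrument scale (slope/intercept), geometric memory, linear drift,
  and Gaussian injection noise (0.5 ‰ default — with 20 retained
  injections and two-point normalization the per-timepoint D/H
  uncertainty lands near the ~3×10⁻⁸ observed in practice);
- ¹⁴C partition: expected oxidized fraction `φ × consumed / CH₄_initial`
  with multiplicative counting noise;
- every experiment includes killed-control twins (zero consumption,
  same noise) and biological replicates (triplicate by default).

All randomness flows from one integer seed; identical configs give
identical output, and the analysis pipeline itself is deterministic
(byte-identical outputs on rerun).
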