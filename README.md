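# soilc13

Natural-abundance ¹³C tracing of soil incubation CO₂: from alkali-trap
titrations to partitioned carbon fluxes, priming effects, and an end-point
aggregate carbon mass balance — with a forward simulator that makes every
stage checkable by recovery.

## The problem

Adding a labile substrate (here cane sucrose, a C4 plant product,
δ¹³C ≈ −12 ‰) to a C3 soil (δ¹³C ≈ −26 ‰) lets the two CO₂ sources be
separated by natural isotopic abundance alone. In a 53-day incubation of
biochar-amended soils (two sites, four field dose classes, ± sucrose,
n = 3), respired CO₂ is caught in NaOH traps replaced at days 1, 3, 7, 14,
28 and 53, quantified by back-titration against HCl, and its δ¹³C measured
on BaCO₃ precipitates. The questions are: how much of the added sucrose-C
mineralizes under each biochar dose, how much extra native soil C is lost
through the priming effect, and how the end-point carbon stock distributes
over aggregate size fractions.

## The model

**Trap chemistry.** CO₂ absorbed by a trap consumes NaOH, so the sample
aliquot needs less acid than a blank:
n(CO₂) = (V_blank − V_sample) · [HCl] · (V_trap / V_aliquot) / s,
with carbonate stoichiometry s ∈ {1, 2} an explicit configuration
(default 2). Multiplying by 12.011 mg C mmol⁻¹ and dividing by dry soil
mass gives mg CO₂-C g⁻¹ soil.

**Two-pool partitioning.** With δ-notation
δ¹³C = (R_sample/R_VPDB − 1)·1000, R_VPDB = 0.0112372, each interval's
total flux C_t splits as

    C₄ = C_t · (δ_t − δ₃) / (δ₄ − δ₃),   C₃ = C_t − C₄

where δ₃, δ₄ are the C3 (soil + biochar) and C4 (sucrose) end members.

**Priming effect.** PE(day) = cumulative C₃ of an amended core minus the
replicate-mean cumulative total CO₂-C of matched unamended cores; negative
PE means suppression of native SOC mineralization.

**Mass balance.** Theoretical mixture C = C₁W₁ + C₂W₂ (biochar and soil C
contents weighted by mass shares); retention = Σᵢ CᵢPᵢ over the four
aggregate sieve classes; loss = theoretical − retention.

**Simulator.** Substrate decays first-order (dS/dt = −k₄S); the native
pool mineralizes at a basal rate modulated for amended cores by a
transient priming pulse 1 + a·(t/τ)e^(1−t/τ). Titration volumes and δt are
rendered by inverting the trap chemistry and mixing pool deltas, plus
seeded Gaussian noise; the noise-free truth is retained for recovery
tests.

## Worked example

```bash
python analysis/01_simulate_incubation.py --seed 1   # 48 cores → results/data/
python analysis/02_compute_fluxes.py
python analysis/03_partition_priming.py
python analysis/04_carbon_balance.py
python analysis/05_treatment_report.py
python analysis/06_parameter_recovery.py
```

With the default design (seed 1) the report step prints, for day 53:

```
cumulative substrate C (mg C g⁻¹):
  Cambisol  control  2.734 ± 0.030 [d]
  Cambisol  medium   4.028 ± 0.040 [a]
cumulative PE (mg C g⁻¹):
  Cambisol  control  0.583 ± 0.028 [a]
  Cambisol  medium   0.186 ± 0.018 [d]
medium-vs-control fold changes at day 53:
  Cambisol  substrate_mineralization   1.473 (~1.5-fold)
  Cambisol  priming_effect             0.319 (~0.3-fold)
```

Read: the medium biochar dose mineralizes the most sucrose (Tukey letter
`a`, mean ± SE over n = 3) while priming the least native C (~0.3-fold the
unamended control) — the dose pattern the simulator's kinetics encode. The
recovery step reports bias ≈ 0 with RMSE set by the measurement noise, and
the balance step confirms that the aggregate-based C loss matches
cumulative evolved CO₂-C per core.

The library surface mirrors the pipeline: `co2_trapped`, `flux_per_gram`,
`delta_to_ratio`/`ratio_to_delta`, `partition_source`, `priming_effect`,
`theoretical_c_content`/`total_c_retention`/`total_c_loss`,
`anova_oneway`/`tukey_hsd`/`fold_change`, `simulate_design`/
`render_measurements`/`recovery_experiment`. See `docs/methods.md` for
assumptions, parameter defaults, and limitations.

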