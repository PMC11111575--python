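# Methods

## Scope and data flow

The package analyses one kind of experiment: a sealed-jar soil incubation
in which respired CO₂ is trapped in NaOH, quantified by back-titration,
and isotopically partitioned between a native C3 pool (soil organic matter
plus aged biochar) and an added C4 substrate (sucrose). Four stages map
onto four modules: `trap_chemistry` (titration → flux),
`isotope_partition` (δ conversions, two-pool split, cumulative series,
priming), `carbon_balance` (end-point aggregate mass balance), and
`treatment_stats` (means ± SE, one-way ANOVA with Shapiro–Wilk and Levene
checks, Tukey HSD letters, fold changes). `data model / io` supplies
validated records and long-format CSV schemas; `synthetic_data` is the
forward model used to verify the whole chain by recovery.

## Trap chemistry

The mole balance assumes the trap is well mixed, so an aliquot scales by
volume (V_trap / V_aliquot); evaporative volume change over the sealed,
humidified jars is neglected. The titration endpoint chemistry is not
derivable from bench descriptions alone, so the carbonate stoichiometry is
an explicit configuration: `carbonate_stoichiometry = 2` (default) counts
the full 2 mol NaOH consumed per mol CO₂ — the usual convention when
carbonate is precipitated with BaCl₂ — while `1` describes a
phenolphthalein endpoint seeing only the first proton. The two differ by
exactly a factor of two; making this visible configuration rather than a
buried constant is the point. Carbon molar mass is fixed at
12.011 g mol⁻¹.

Apparent negative fluxes (sample titration exceeding the blank) are
retained with a warning and propagate as negative interval masses;
deleting them would bias cumulative sums upward. Blank handling is either
`paired` (each record carries its own blank, the default for simulator
output) or `per-batch-mean` (replace with the mean of a batch's blank
jars, batches keyed by site × interval).

## Partitioning and priming

Partitioning follows the linear δ-mixing form C₄ = C_t(δ_t − δ₃)/(δ₄ − δ₃)
applied per interval — each interval's δt applies to that interval's flux
only; cumulative δ is never used for partitioning (it is only reported via
the mass-weighted mixture delta). Partitioning on ¹³C atom fractions
instead of δ values changes the split by < 0.1 % of C_t for end members
near −26/−12 ‰; a test quantifies this and the implementation keeps the δ
form deliberately, as it is the form in standard use.

The C3 end member for an amended core is taken per (site, dose class,
interval) from the mean measured δt of the matched unamended cores, which
respects any biochar-induced shift in the native signature, falling back
to the bulk-soil δ₃ column when no unamended cores exist. Unamended cores
are treated as single-pool (their substrate share is identically zero)
rather than partitioned against their own mean, which would only inject
noise. End members closer than `min_delta_separation` (default 5 ‰) are a
fatal error: the divisor in the mixing equation is then dominated by
measurement uncertainty.

Out-of-range mixing fractions are clamped to [0, 1] by default with a
per-record flag, and the raw fraction is kept in the output; clamping
preserves the conservation identity C₃ + C₄ = C_t because C₃ is always
computed as the complement. The priming baseline averages unamended
replicates (mean) before subtraction; replicate-paired subtraction is
available as a sensitivity variant.

## Mass balance

The balance works in g C kg⁻¹ (numerically equal to mg C g⁻¹, so flux and
balance results compare directly). Aggregate proportions must sum to 1
within a tolerance (default 0.02, absorbing sieving losses); within the
tolerance raw proportions are used as-is — renormalization is opt-in and
logged, since the retention sum is defined on raw proportions. Negative
loss (retention above theoretical content) is reported, not clipped: it is
diagnostic of inconsistent inputs. A helper converts a field application
rate (Mg ha⁻¹) to a biochar mass share W₁ assuming uniform incorporation
(default 0.1 m depth, bulk density 1300 kg m⁻³); these are labelled
assumptions, and the balance itself takes W₁ as input.

## Statistics

Comparisons are made within each sampling date (the report drivers loop
over days) on cumulative values by default. Assumption-check failures
(Shapiro–Wilk on residuals, Levene across groups, both at p < 0.05)
produce warnings, not an automatic nonparametric fallback. ANOVA uses the
classical between/within decomposition; Tukey HSD comes from statsmodels,
with a compact letter display built by the insert-and-absorb algorithm on
the pairwise significance matrix. Fold changes are reported at full
precision in machine output and one decimal in human-readable text.

## The simulator

What it emulates: the full factorial design (2 sites × 4 dose classes ×
± sucrose × 3 replicates, traps replaced at days 1, 3, 7, 14, 28, 53);
first-order substrate mineralization with dose-dependent rate k₄;
a constant basal native-C flux with a dose-dependent transient priming
pulse; isotopic mass balance (δt is the exact mass-weighted mixture of the
pool deltas before noise); and measurement rendering that inverts the same
trap stoichiometry the pipeline applies, so the zero-noise pipeline output
equals the truth to floating-point accuracy.

Parameter defaults and why:

| parameter | default | rationale |
|---|---|---|
| substrate C added | 4.21 mg C g⁻¹ | 10 mg sucrose g⁻¹ × 144/342 C mass fraction |
| k₄ by dose | 0.020 / 0.025 / 0.060 / 0.040 d⁻¹ (control/low/medium/high) | day-53 cumulative substrate C spans ≈ 2.7–4.0 mg C g⁻¹ with the medium dose highest, the headline dose pattern |
| basal flux by dose | 0.040 / 0.038 / 0.034 / 0.036 mg C g⁻¹ d⁻¹ | ≈ 2 mg C g⁻¹ native C over 53 d, mildly suppressed by biochar |
| priming amplitude a by dose | 1.15 / 0.90 / 0.40 / 0.70 | day-53 PE ≈ 0.6 (control) down to ≈ 0.2 (medium) mg C g⁻¹; medium dose primes least |
| pulse timescale τ | 5 d | the pulse g(t) = (t/τ)e^(1−t/τ) then peaks, interval-integrated, in the day 7–14 trap and gains < 5 % of cumulative PE after day 28 — a transient priming episode that is over by week four. Larger τ (≳ 7 d) leaves a double-digit share of PE after day 28, contradicting the transient behaviour the simulator is meant to encode |
| δ₃ by site | −26.36 / −24.78 ‰ | C3 soil end members (Cambisol / Fluvisol) |
| δ₄ | −11.97 ‰ | cane-sucrose end member |
| δt noise sd | 0.12 ‰ | the sucrose signature's reported spread, a realistic IRMS-scale |
| titration noise sd | 0.05 mL | engineering choice for an auto-titrator reading |
| dry soil per jar | 25 g | keeps every interval's CO₂ within the 20 mL 1 M NaOH trap's capacity so titration volumes stay in [0, V_blank]; per-gram results are mass-invariant, and trap saturation is deliberately not modelled |
| mixture C₁, C₂ | 600 g C kg⁻¹ biochar; 12 / 10 g C kg⁻¹ soil | typical wood biochar and arable topsoil contents |

The dose tables are illustrative of the qualitative pattern (medium dose:
most substrate mineralization, least priming), not fitted to any measured
series. All randomness derives from one seed via `SeedSequence.spawn`, one
child stream per core, so any single core's data can be regenerated in
isolation; a fixed seed yields byte-identical CSV output.

Truth-side invariants the simulator guarantees: cumulative substrate C
never exceeds the substrate added (noise can push the *estimate* above it —
which is exactly how over-unity recoveries arise in real datasets, and why
the pipeline surfaces rather than hides clamping); rendered δt at zero
noise always lies between the end members; priming amplitude 0 makes
amended and unamended native fluxes identical.

What it does not emulate: microbial community or pore-structure dynamics,
trap saturation or capture efficiency, isotopic fractionation during
respiration, autocorrelated or heteroscedastic noise, aggregate turnover
during the incubation. Passing recovery tests therefore demonstrate the
pipeline's correctness as an inverse of this forward model, not the
realism of any particular field dataset.

## Numerical choices

Conservation (C₃ + C₄ = C_t) holds exactly by construction. The
mix-then-partition round trip is verified to 10⁻¹² relative to the total
mixture mass — the natural scale, since the error relative to a vanishing
pool is unbounded for any floating-point implementation. End-to-end
zero-noise identity is asserted at 10⁻⁹ relative with a 10⁻¹² absolute
floor. Degenerate inputs fail loudly: δ ≤ −1000 ‰ (non-positive ratio),
non-positive isotope ratios, zero total pool mass, zero control mean in a
fold change, zero within-group variance with unequal means in ANOVA.

Monte-Carlo work (null-priming recovery, coverage) runs on a reduced
design — one site, control dose, ± sucrose, three replicates — because the
estimator properties under test do not depend on the number of treatment
cells; 200 replicate datasets give a standard error of ≈ 0.003 mg C g⁻¹ on
the mean day-53 PE.

## Known limitations

Two-pool partitioning cannot separate soil from biochar carbon (both are
C3); a second tracer would be needed. The priming estimate inherits any
bias in the unamended baseline — with three replicates the baseline mean
is noisy, and the matched-δ₃ estimator is mildly nonlinear in that noise
(second-order small at the default 0.12 ‰). The balance cross-check
assumes all evolved CO₂-C is counted; trap saturation, if it occurred,
would appear as retention exceeding expectation rather than being
detected directly.
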