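# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic-data generator does and does not establish.

## Quantitation model

**Calibration.** Absolute quantitation rests on a spike-in standard of known
molar amounts (six groups of eight proteins in decade steps from 0.5 fmol —
the layout of the commercial UPS2 standard). Per biological replicate we fit
ordinary least squares of log₁₀(amount) on log₁₀(intensity) over the
*detected* standards of that replicate and use the fitted line as a direct
plug-in predictor of amount from intensity. Two deliberate choices:

- *Regression direction.* Amount is regressed on intensity, not the reverse.
  The two directions give different estimators; regressing amount on
  intensity makes prediction a direct plug-in and is the natural reading of
  "amount plotted against intensity". On noise-free data both coincide.
- *Detected-only standards.* Standards censored below the detection limit in
  a replicate are excluded from that replicate's fit rather than imputed.
  With the default generator the lowest spike group (0.5 fmol → 5×10⁵
  intensity units) sits above the detection limit, so in practice all 48
  standards contribute unless noise pushes one under.

**Concentrations.** amount(fmol)/volume(nl) × 10⁻⁶ gives mol/L; the volume
model is a 50 nl nucleus and a 500 nl yolk-free cytosol (cytosol:nucleus =
10). Concentrations are averaged across the biological replicates in which
the protein was detected — no zero-filling, which is conservative against
censoring bias. The default average is arithmetic on the linear scale (the
natural reading of "average concentration"); a geometric option exists
(`RunConfig(averaging="geometric")`). The simulator emits biological
replicates only; if technical replicates exist upstream they are expected to
be combined before the table reaches this package.

**Ratios and censoring.** N:C is the ratio of the averaged concentrations.
Proteins detected in a single compartment get a status flag (`nuc_only` /
`cyt_only`) and no finite ratio; substituting a detection-limit pseudo-
concentration is available behind `RunConfig(pseudo_conc=...)` but off by
default, because pseudo-ratios are bounds, not measurements. Reports carry
full precision; the conventional "300:1"-style rounding is presentation-only
(`format_ratio`).

## Filters

Partition mode: records with minimum peptide PEP > 0.01 are dropped, and
proteins carrying an "only identified by site" flag detected in only one
compartment are removed (the flag is tolerated for proteins seen in both
compartments, where the identification is corroborated). Cargo mode:
site-flagged proteins in the RanGTP-bound sample are excluded outright; the
frog profile additionally applies the PEP filter and requires ≥ 2 unique
peptides. PEP is consumed at protein level as the minimum peptide PEP
because the package operates on protein summaries, not MaxQuant peptide
tables.

## Cargo scoring and categories

Molar fractions are computed per sample over detected proteins, so they sum
to 1 by construction. When a protein is undetected in the input or minus-Ran
sample, the missing intensity is replaced by a detectability baseline — the
median of the k = 30 least abundant detected proteins of that sample, with
ties broken by a stable (intensity, protein id) sort — and the resulting
enrichment/stimulation is flagged `*_is_bound_estimate` (a lower bound).
For proteins undetected in the *bound* sample the same baseline bounds their
enrichment from above, which is what the depletion (non-binder) call needs.
Estimates are never silently mixed with measurements; consumers can exclude
them, as scatter-style displays conventionally do.

Categories are a first-match ordered rule list (the source material presents
them as a partition without stating precedence):

| category | rule (frog defaults) |
| --- | --- |
| A1 | stimulation ≥ 500 and enrichment ≥ 3 and bound molar fraction ≥ 1e-4 |
| A2 | enrichment ≥ 100 and stimulation ≥ 10 |
| B | exactly one A1 criterion relaxed by factor 1/3, the other two at full strength |
| low_abundant | detected only in the bound sample, below the A molar-fraction gate |
| non_binder | in input at molar fraction ≥ 1e-5 with enrichment ≤ 0.2 |
| ambiguous | residual |

Only three of these numbers are published values (A1 stimulation 500 and
enrichment 3 for the frog; A2 enrichment 100). The A abundance gate (1e-4),
A2 relaxed stimulation (10), B relaxation factor (1/3), and the non-binder
depletion ceiling (0.2) with its input-abundance floor (1e-5) are package
defaults standing in for unpublished supplementary threshold tables; all are
configurable per species, and the human/yeast profiles default to the frog
profile. The abundance gate is an absolute molar fraction rather than a rank
cut — the source is ambiguous ("most abundant proteins"), and an absolute
gate is reproducible across experiments of different depth. Transport-
machinery proteins (NUPs, NTRs, NPC constituents, CRM1 cofactors) are
assigned their class from a list regardless of scores, since they are part
of the transport system, not cargo.

## The synthetic world

The generator emulates the *conditions* of the two experiments, not their
biology:

- **Abundance**: log-uniform total concentration over 5 decades
  (10⁻¹⁰–10⁻⁵ M), matching the stated dynamic range of reliable
  quantitation; a log-normal alternative is available.
- **Compartments**: 22% nuclear-only, 21% cytosolic-only, 57% shared
  (mirroring the measured 1126/1059/2821 split), shared proteins splitting
  by a log-normal N:C ratio (σ = 1.2 decades).
- **Noise**: multiplicative log-normal with σ = 0.18 in log₁₀ — chosen so
  that naive single-replicate recovery error is on the "within a factor of
  ~2–2.5" scale; per-replicate intensity variance is not published, so this
  is a stated default, not a fit.
- **Censoring**: pure left-censoring at a hard detection limit (10⁵
  intensity units at a response factor of 10⁶ per fmol), the simplest
  mechanism consistent with intensity-dependent missingness.
- **Proteoforms**: 1 + Poisson(0.9) proteoforms per protein (≈1.9 on
  average, matching the observed 9573 proteoforms over 5006 unique
  proteins), amounts split by a symmetric Dirichlet(α = 2).
- **Binding**: linear two-term occupancy — input ∝ abundance, minus-Ran ∝
  background × abundance, plus-RanGTP ∝ (background + strength) × abundance.
  The source gives only resulting ratios, no binding model; this is the
  simplest mechanism that reproduces them.
- **Strata**: 5% strong cargo, 10% weak cargo, 15% background-only, 70%
  non-binder (cargo strength exactly 0 for the latter two; non-binders also
  get lower background binding, 10⁻⁵–10⁻⁴ vs 10⁻⁴–10⁻² occupancy).

**The strong-cargo stratum is defined by recoverability.** Bound-sample
molar fractions are relative quantities, so a stratum whose strength ×
abundance product spans too many decades necessarily pushes its lower tail
below any fixed abundance gate — even noise-free. Strong cargoes therefore
draw abundance from the upper two decades (≥ 10⁻⁷ M) and strength from
20–200× background, which makes their *noise-free* scores clear the A1-or-B
gates by construction (stimulation ≥ 2000×, enrichment ≈ 2–20×, molar
fraction at or above the gate). Recovery of strong cargoes (90–96% into A∪B
across seeds at n = 2000) consequently measures the effect of noise,
censoring, baseline imputation and identification-quality filtering — not of
an arbitrarily chosen abundance floor. Proteins with strong binding but low
abundance are real, and the category system *should* file them under
low-abundant/ambiguous; they are just not members of this stratum.

What a green test does **not** establish: the generator has no peptide or
spectrum level, no sample-to-sample batch structure, no intensity-dependent
noise heteroscedasticity, no correlated contaminant behaviour, and no
piggyback binding (complex members sharing one NES). Counts per category at
full dataset scale depend on the real abundance distribution and are not
reproduced — only the printed worked examples and the generator-oracle
properties are.

## Numerical choices

- Zero intensities on input are converted to missing (exported tables use 0
  for "not detected").
- Proteoform merging: intensity sums treat missing as 0 unless every member
  is missing (then missing); unique peptides add; PEP takes the minimum;
  the site flag survives only as a conjunction.
- Calibration r² is reported as exactly 1.0 when residuals vanish to float
  precision, avoiding spurious 1 − 1e-16 artifacts.
- Density curves: Gaussian KDE with Silverman bandwidth per group (absolute
  bandwidth overridable, in log₁₀ units), evaluated on a shared grid that
  extends eight bandwidths past the data so each rescaled curve's on-grid
  mass equals its group share to well below 1e-9. Degenerate groups (n < 2
  or zero variance) get a hand-placed kernel of width 0.2. Censored
  one-compartment proteins are reported as end-of-axis counts, not folded
  into the kernel — their handling in panel-style figures is unspecified,
  and mixing bounds into a density would distort it.
- Contaminant curation: removed = flagged \ keep-list, kept = flagged ∩
  keep-list, so flagged = removed + kept always; keep-list entries that were
  never flagged are counted separately and not applied.

## Limitations

- Category boundaries beyond the three published gate values are package
  defaults; absolute category censuses are therefore comparable only within
  a configuration.
- The "ambiguous" class is the residual of the rule list and will not match
  any manually curated continuum protein-for-protein.
- Baseline imputation makes estimate scores depend on sample depth (the
  30-protein window is an absolute count, as specified).
- The pipeline consumes protein-level tables; protein inference, peptide
  filtering inside the search engine, and ortholog mapping are upstream and
  out of scope.
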