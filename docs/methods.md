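# Methods

## Data model

The identification unit is the protein group as exported by the upstream
search engine: an opaque accession string, never split into individual
accessions. Raw intensity is the summed peptide signal of a protein
group in one LC-MS/MS run, in arbitrary instrument units; 0 and a
missing cell both mean "not detected" and are treated identically.
Contaminant-database and decoy ("reverse") rows are removed before any
analysis; upstream peptide/protein FDR control is assumed done and is
out of scope.

A screen design maps each run code to (bait-or-control, condition,
replicate, role). Validation enforces triplicates, unique run codes, and
exactly one control group of each type per condition. The packaged
default design is the 8-bait × 3-condition *E. coli* replication screen
(90 runs).

## Qualitative strategy

Detection = raw intensity > 0. Hits for (bait, condition) are the
three-way intersection of the experimental replicates' detection sets
minus the **union** of all six control replicates' detection sets. The
union reading (rather than the controls' triplicate cores) is the
stricter interpretation of "absent in all replicates of both controls"
and is the one implemented; it is also conservative — enlarging any
control detection set can only remove hits (a tested invariant).
Replicate reproducibility is summarised as |core| / |union| over the
three replicates (NaN when nothing was detected at all).

## Quantitative strategy

Per run: value = log10(raw / median of the run's nonzero raws) for
detected proteins, 0 otherwise (the raw-0 → normalized-1 → log-0 rule).
An all-zero run yields an all-zero column and a logged warning.

Global dispersion: variance and SD pooled over *every* transformed value
of one condition — all experimental and control runs, placeholder zeros
included. Default denominator n−1 (`sd_mode="sample"`);
`"population"` available. This σ is deliberately generous: it reflects
between-protein abundance spread, not replicate error, so the z-test is
conservative.

Per (bait, condition) and per protein detected in ≥1 experimental
replicate: av_exp, av_c1, av_c2 are the means of the three transformed
replicate values. Against each control:

1. av_ctrl = 0 → verdict `absent_in_control`, no test. Note this is an
   exact floating-point test on the *average*: a protein whose three
   control values are all exactly 0 (not detected, or detected exactly
   at the median) triggers it. The literal rule is kept for
   reproducibility; the at-the-median coincidence has measure zero in
   real data.
2. Otherwise the enrichment Δ = av_exp − av_ctrl is rescaled to log2
   units, Δ/log₁₀2, and must reach 1.5 (inclusive). The averages are
   already logarithms, so rescaling the difference is the only coherent
   reading of a "log2 magnitude ratio" of intensities; a mode applying
   the 1.5 directly to the log10 difference is provided
   (`fold_scale="log10"`) because the wording is ambiguous.
3. Passing proteins get a one-sided upper-tail z = Δ/σ (verdict
   `enriched`); `zscore_scale="mean_of_three"` divides σ by √(3/2) —
   i.e. multiplies the denominator by √(2/3), the SD of a difference of
   two means of three — for users who read the z as a two-sample test on
   means. p-values are BH-adjusted within the family of proteins that
   were actually tested for that (bait, condition, control); p-values
   only exist after the fold filter, so the family is defined after it.
   `bh_family="per_sample"` pools both controls' tests instead.

Final hit: present in all three experimental replicates (raw > 0) and,
for each control, verdict `absent_in_control` or `enriched` with
adjusted p ≤ 0.01. Records are emitted for *all* proteins detected in
≥1 experimental replicate, flagged by `final_hit`, so every intermediate
quantity can be deposited and re-examined.

### Numerical choices

- Comparisons are exact ≥/≤ on doubles; no epsilon fuzzing. The fold
  boundary is inclusive.
- σ = 0 with a passing fold yields p = 0 by convention (logged).
- Reductions (triplicate means, pooled variance) are accumulated
  sequentially in a fixed run-major, row-major order; log10 and the
  normal tail (erfc) are computed with scalar libm calls. Identical
  inputs therefore give bit-identical outputs, and the pipeline matches
  an independently coded straight-line transcription of the processing
  steps exactly — a property the test suite asserts on 100 random
  screens.
- BH adjustment is implemented directly (step-up with stable tie
  ordering, terms computed as p·m/k) and cross-checked against
  statsmodels in the tests.

## Synthetic data generator

The generator emulates the failure modes the double-control design
exists to separate, one protein class each: `resin_binder` (present in
every sample), `tag_binder` (present wherever a tag is present — all
experiments and control 2), `bystander` (present everywhere),
`specific_prey` (either present *only* in its bait's pull-downs,
`prey_mode="exclusive"`; or present everywhere with +`effect_log10` in
its bait's pull-downs, `"enriched"`), and `bait` (present everywhere —
it is a native protein of the background strain — and boosted
`bait_log10_boost` in its own pull-down). Two prey modes exist because
the qualitative strategy can only detect exclusive presence, while the
quantitative strategy detects both — the motivation for having a
quantitative variant at all.

Intensities are lognormal: 10^(baselineᵢ + class/role offset +
N(0, replicate_noise_sd)), baselineᵢ ~ N(baseline_log10_mean,
baseline_log10_sd) drawn once per protein, then zeroed with probability
`dropout_prob`. One generator seeded per dataset; draw order is fixed
(baselines first, then per run: noise vector, dropout vector, drawn
regardless of parameter values) so datasets are stable across versions
and comparable across parameter settings.

Defaults are the package's benchmark world: 300 proteins, 3 baits ×
10 exclusive preys, 30 resin binders, 20 tag binders, baseline
10^N(7, 0.5) (Orbitrap-scale), effect 2.0 log10, replicate noise
0.15 log10, no dropout, bait boost 2.0 log10, seed 42. The abundance
and noise scales are the one free choice; 0.15 log10 (~40% CV) is a
typical label-free replicate spread and 0.5 log10 a modest dynamic
range.

What a green benchmark does **not** establish: the generator has no
peptide-level structure, no intensity-dependent dropout (missingness is
uniform, not left-censored), no correlated background (resin binders
vary independently), and the median-normalization assumption (most
proteins unchanged) is true by construction. Recovery of planted truth
here validates the arithmetic and the filtering logic, not performance
on real lysates.

## Network reporting

One edge per final hit, attributed by condition and evidence type:
`absent_in_controls` (no weight — no enrichment against control 2 is
defined) vs `enriched` (weight = log2 fold enrichment against
control 2, the quantity conventionally mapped to edge width). Prey
functional categories are user-supplied curation over a packaged
10-label vocabulary; unknown preys are `unassigned`.

Summaries: 7-region Venn counts of one bait's hit sets across three
conditions (regions partition the union); pairwise bait similarity,
default 100·J(Sᵢ,Sⱼ)·(|Sᵢ∪Sⱼ|/|⋃ₖSₖ|) — percent shared interactants
weighted by the pair's share of the whole screen, diagonal 100 by
definition — with plain Jaccard as the alternative, both labelled in the
output filename ("weighted-averaged" similarity is underspecified, so
both defensible readings are provided); volcano tables with
absent-in-control proteins flagged and *not* given fabricated p-values.
Exports: SIF (interaction type `bait-prey`), GraphML with all
attributes, flat TSV edge/node tables.

## Known limitations

- The absence rule is an exact zero test on an average of logs; see
  above.
- Global σ pools biological variation across proteins, making the test
  conservative for low-variance proteins and anticonservative for none;
  no per-protein variance model is attempted (by design — that would be
  a different method).
- No imputation beyond the 0→1 rule; no isotope-label quantification;
  no empirical-Bayes interaction scoring (SAINT/CompPASS are different
  methods and out of scope).
- The xlsx reader expects protein lists laid out like the TSV dialect
  (per sheet); exotic spreadsheet layouts need pre-wrangling.
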