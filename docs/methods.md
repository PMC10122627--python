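# Methods

## Model and procedure

`varburden` tests, per gene, whether a case cohort carries an excess of
qualifying missense variants relative to a population control cohort that is
observable only through per-site summary statistics (AC, AN, nhomalt).  The
collapsing unit is dominant: a subject is a carrier if they carry at least
one qualifying alternate allele anywhere in the gene.  Two 2×2 tables are
tested per gene with the exact hypergeometric upper tail (one-sided Fisher
exact test, enrichment direction only):

* **subjects** — case carriers out of N_case versus estimated control
  carriers out of N_ctrl;
* **alleles** — summed case alternate alleles out of 2·N_case chromosomes
  versus summed control AC out of 2·N_ctrl.

Family-wise error is controlled by Bonferroni over the m genes of the run's
panel (m is never hard-coded: a 3-gene replication run is corrected by 3).
Odds ratios use (a·d)/(b·c) with the Haldane–Anscombe +0.5 correction at
zero cells, flagged when applied.

### Qualifying variants

A variant qualifies for a gene iff it (i) lies within the gene's coding
exons padded by 5 bp on each side, (ii) is annotated `missense_variant` in
any transcript (a `canonical`-only policy is available via
`AnnotationSpec(transcript_policy="canonical")`), and (iii) is a strict SNV.
Indels are excluded categorically: their artefact rate differs too much
across sequencing platforms for cross-platform case/control comparison.
Controls contribute qualifying variants across the *entire* gene, exactly as
cases do — the selection is not restricted to positions observed in cases.
Panel genes with zero qualifying variants still yield a result row (p = 1),
keeping the Bonferroni denominator equal to the panel size.

### Case-side processing

Multi-allelic records are expanded to one record per alternate allele, with
per-sample dosages preserved (splitting conserves each sample's total
alternate allele count; this is property-tested exhaustively).  Indel
left-alignment is not performed because indels never reach the analysis.
Missing genotypes count as homozygous reference and the case denominator is
the full cohort at every site, mirroring the fixed-denominator treatment the
summary-statistic control side imposes.  Site filters: mean read depth
(over samples with a DP value) must be ≥ 10 — the boundary is inclusive,
reading "below 10 excluded" literally — while the optional QD filter is
strict (> 4), again literally.  Sites with no depth (or QD) information are
retained with a warning rather than silently dropped.

### Control carrier approximation

True control carrier counts are unknowable from summary data.  Two
estimators are provided:

* `sum_ac` — Σ AC over the gene's qualifying sites;
* `sum_ac_minus_hom` (default) — Σ (AC − nhomalt), which counts each
  homozygote once instead of twice.

Both are overestimates whenever one individual carries several qualifying
variants in the gene, and both are capped at N_ctrl.  Overestimating control
successes can only increase the upper-tail p of the case-enrichment test, so
the approximation is conservative; the calibration experiment verifies this
empirically and the acceptance checks assert it is never anti-conservative.
The default subtracts homozygotes because a published discovery table we
reconstructed is consistent with the homozygote-adjusted sum and not with
the plain sum on at least one heavily mutated gene; the plain sum remains
one flag away.

### Allele-table denominators

The default control chromosome total is 2·N_ctrl.  Real summary extracts
call fewer alleles at most sites (AN < 2N).  Reconstructing a published
discovery table showed that its allele p-values are jointly consistent with
per-gene denominators around 98–99% of 2N (i.e. the resource's true AN) and
not exactly with 2N; since per-gene AN cannot be recovered from a printed
table, the package defaults to the transparent 2N construction and exposes
`allele_denominator="an"` (using the gene's largest observed per-site AN)
for data that carries AN.  For the same reason two printed p-values differ
from what the printed counts imply under any fixed construction
(≈ 0.56 vs 0.57; ≈ 7.0×10⁻³ vs 6.2×10⁻³); the corresponding acceptance
checks assert the printed values and fail, documenting the discrepancy
rather than hiding it.  Note the allele table is only well-formed while
Σ dosage ≤ 2N per cohort; a gene whose summed case alleles exceed the case
chromosome count raises a consistency error naming the gene.

## Synthetic cohorts

The generator emulates the targeted study design: N_case = 184 cases with
genotypes and N_ctrl = 56,885 summary-statistic controls over an 8-gene
autosomal panel (all defaults configurable).  Per gene it draws 30 rare
sites (allele frequency uniform in 10⁻⁴–10⁻³) and 5 common sites
(10⁻²–10⁻¹), labelling each missense with probability 0.7.  Genotypes follow
Hardy–Weinberg proportions with per-site independence; control summaries
draw hom ~ Bin(n, f²) then het ~ Bin(n − hom, 2f(1−f)/(1−f²)), so
2·nhomalt ≤ AC ≤ AN holds by construction.  A per-gene enrichment factor
γ ≥ 1 multiplies case allele frequencies (capped at 0.5), optionally
restricted to common and/or missense sites.  Spike-ins exercise every
exclusion rule: indels (5%), multiallelic records (5%, drawn jointly so a
sample never exceeds two alternate alleles at a position), off-exon sites
beyond the pad (5%), low-depth sites (5% with mean DP < 10), low-QD sites
(5% with QD ≤ 4), genotype missingness (1%) and control AN missingness (1%).

What the generator does **not** emulate: linkage disequilibrium (the test
treats sites exchangeably, so LD realism would not change its null
behaviour, but real per-gene carrier counts are correlated across sites),
population structure and ancestry mismatch, relatedness, platform-specific
error profiles beyond the DP/QD fields, and annotation disagreement between
case and control sources.  Passing calibration on these synthetic cohorts
therefore demonstrates the statistical machinery, not robustness to
confounding in real case/control comparisons.

## Calibration and power experiments

`run_calibration_experiment` runs the pipeline per replicate on in-memory
objects (site simulation → genotype draws → qualifying selection →
collapsing → tests), skipping only VCF serialisation, which is covered by
round-trip tests and the end-to-end demonstration.  Scaled-down problem
sizes keep the experiments at desk scale: 200 cases, 5,000 individually
simulated controls, 8 genes; 1,000 replicates for null calibration and 200
for recovery.  Under the null the subject test's empirical type-I error at
α = 0.05 is compared against nominal plus two Monte-Carlo standard errors
(Fisher's exact test is conservative on discrete tables, so the observed
rate sits below nominal: ≈ 0.03–0.04 for exact carriers, far lower under the
summation approximations), and the approximation p-values are checked to
never fall below the exact-carrier p on any paired table.  Under γ = 4 on
one gene's common missense sites, recovery is the fraction of replicates in
which that gene — and, for exclusive recovery, only that gene — falls below
the Bonferroni threshold; both exceed 0.99 at these sizes.

## Numerical choices

* Fisher p-values via `scipy.stats.hypergeom.sf` (log-space internally);
  the test suite compares against exact integer enumeration
  (`math.comb`) for every margin with N ≤ 60 (agreement to < 10⁻¹²
  relative).
* p-values are reported at full precision; the display layer floors at
  `< 2.2e-16`, the conventional exact-test floor, with 3 significant
  figures otherwise; odds ratios are rounded to 3 decimals in the table.
* Untestable tables (zero case margin) raise rather than return 1.
* Coordinates are 0-based half-open internally (BED convention); variant
  keys `chrom:pos:ref:alt` are 1-based (VCF convention).
* Interval membership uses bisection over merged sorted exon intervals.
* All randomness flows from one `numpy.random.Generator`; a fixed seed
  makes panels, cohorts and written VCFs byte-identical.

## Known limitations

* The het/hom case columns count subjects non-exclusively (a subject with
  both a het and a hom genotype in a gene appears in both); the distinct
  carrier count is reported separately and used for the subject test.
* Control qualifying selection trusts the control sites' own consequence
  annotation; no re-annotation or cross-source harmonisation is attempted.
* No covariates, ancestry adjustment, sex stratification or
  variance-component (SKAT-like) tests; the model is a pure 2×2 collapsing
  test per gene.
* The carrier approximation's conservativeness is one-directional: power is
  sacrificed, never type-I error.
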