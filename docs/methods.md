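# Methods

## The analysis model

The pipeline treats an annotated exome-sequencing cohort as a list of
variant rows (one per variant, with carrier case IDs and predictor
annotations) plus per-variant allele frequencies from ordered population
sources. Association is allelic and unadjusted: for each candidate, a 2×2
allele-count table is formed with the case cohort on one margin and a
reference population on the other,

|            | alt | ref |
|------------|-----|-----|
| cases      | a   | b   |
| population | c   | d   |

where `a` counts alternate alleles among carriers (het = 1, hom = 2),
`b = 2·n_cases − a`, and the population counts are reconstructed from the
resolved allele frequency: `c = round(AF × AN)` (half-up), `d = AN − c`.
The odds ratio is the cross product `(a·d)/(b·c)`; inference is Wald on
the log scale with `SE = √(1/a + 1/b + 1/c + 1/d)`, a two-sided normal
test, and the 95% quantile fixed at 1.959964. Multiplicity over the
candidate set is controlled by the Benjamini–Hochberg step-up
(`q_(i) = p_(i)·n/i` on the ascending sort, running-minimum
monotonization from the largest rank, capped at 1, stable-sorted ties).

The Wald construction is an inference choice, not a given: no test is
named alongside the published table this package reproduces. It is
adopted because it is the only standard construction that recovers the
published P column from the published (OR, CI) pairs — the package
provides `p_from_or_ci` as the verification instrument, and the test
suite confirms agreement at three decimals for the checkable rows
(CAPN1 0.012, LIMS1 0.007, UNC45A 0.002).

### Population panel allele numbers

Panels publish frequencies, not counts, so reconstruction needs an allele
number per source. The defaults — 2654 for the regional (FINRISK-like)
panel and 25000 for the national (gnomAD-FIN-like) panel — are
reverse-derived calibration constants: they are the values under which the
reconstructed tables reproduce the published ORs and CIs to printed
precision (CRTAC1 5.27 (1.31–21.22), CAPN1 6.33 (1.50–26.65), UNC45B
≈14.9 from the national source). Neither number is an independent fact
about those panels; both are ordinary config keys.

## Filter cascade

Stage order: frequency resolution → rarity → recurrence → prediction →
flagged genes. All rules are conjunctive, so the surviving set does not
depend on stage order (verified against an order-free brute-force
evaluation); the order only determines which rule is blamed in the
exclusion log, and the per-stage counts telescope exactly. Numerical
choices, all strict inequalities: MAF < 0.005 in **every** non-missing
source (a conservative AND — a variant common in any panel is not rare),
carrier count ≥ 3, CADD > 20, tier scores > 0.7. Missing annotations fail
their clause and are attributed to `insufficient_annotation`; a variant
with no frequency in any source is excluded as `no_population_frequency`.
Stop gains are gated on MutationTaster disease-causing with CADD recorded
but not required: truncation is damaging by mechanism, and this is the
reading under which the published stop-gain row (MT=DC, CADD 44.0, no
SIFT/PolyPhen calls) passes without inventing an extra rule.

One documented discrepancy: the accompanying text says nine missense
variants exceed the 0.7 tier threshold, but ten published rows satisfy
the strict rule (the CRTAC1 MutScore 0.764 is the tenth). The package
follows the printed rule and reports ten.

ClinVar-pathogenic matches are reported in a side table and never enter
the cascade: such variants are carried by single individuals, below the
recurrence bar, but remain clinically reportable. Matching is on
(chrom, pos, ref, alt); an rsid that agrees while coordinates differ is
logged, not joined.

## Biochemical profile

Substitutions are classed as transition/transversion; protein changes are
parsed from `p.Arg153Cys`-style notation. The amino-acid class table is
shipped as data (`data/aa_classes.tsv`), not code, because the class
vocabulary (aliphatic/aromatic/neutral/acidic/basic/unique; dipole; size)
is standard while the exact partition of the 20 residues is a curation
choice: the default uses unique = {C, G, P}, acidic = {D, E},
basic = {H, K, R}, aromatic = {F, W, Y}, aliphatic = {A, I, L, V, M},
neutral = {S, T, N, Q}, residue volumes (Å³) cut at <120 / 120–170 / >170
for size, and ordinal dipole classes low/moderate/high (nonpolar,
polar-uncharged, charged). Output metadata should be read with that
provenance in mind; the table is swappable. PTM matching is
exact-position by default (a ±window exists for sensitivity analysis
only); Pfam-style domain intervals are 1-based inclusive, with
overlapping intervals resolved deterministically to the smallest start.

## Interaction compendium and enrichment

"Multi-validated" is interpreted as ≥ 2 distinct supporting publications
for physical BioGRID-style edges (the threshold is a config key);
pair-list (systematic reference-interactome) edges are exempt, since each
derives from one screen publication. Self-loops are dropped; a query with
no qualifying partner is a valid empty set.

The heart-enhancement test is an upper-tail hypergeometric P(X ≥ k) with
background N = proteins carrying a staining annotation, K = those with
high/medium cardiomyocyte staining, n = compendium interactors within the
background, k = the heart-enhanced ones. The background is deliberately
the staining-annotated universe rather than the whole proteome, and the
unit is proteins rather than interaction events; both choices are
genuinely open given the ambiguity of "enrichment for interactions with
heart-enhanced proteins", and the protein-level orientation is the
default because it is invariant to how many query proteins share a
partner. Matrisome category tests are plain Pearson chi-squares of
observed category counts against background proportions, no continuity
correction, with warnings below expected count 5. Published enrichment
p-values for these tests depend on the database snapshots used at the
time and are therefore validated here only as machinery, on planted
fixtures.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with the reference study's conditions as defaults: 127 cases, true
population MAFs uniform on (0.0005, 0.0045) — inside the rarity bar even
after per-source count rounding — allele numbers 2654/25000 with 10%
regional missingness, ~5% stop gains, and planted odds ratios log-uniform
on (2, 20) for a 20% causal fraction. Carrier counts are drawn
`Binomial(2·n_cases, f_case)` under the odds-multiplication model
`odds_case = OR × odds(pop_af)`, so the estimand of the downstream
estimator equals the planted OR exactly; draws exceeding n_cases are
rejected and resampled, keeping cohorts heterozygous-only (a switch
admits homozygotes). Predictor scores are class-conditional (causal:
SIFT D, damaging PolyPhen-2, CADD ~N(28,3), Varity/MutScore ~Beta(8,2);
benign: diffuse mixtures, CADD ~N(14,5)⁺, scores ~Beta(2,8)). Networks
connect background proteins to query proteins independently with
probability `edge_prob`, multiplied by `heart_enhanced_bias` (capped at
1) for the heart-enhanced fraction. One global seed feeds named
`SeedSequence` substreams (variants, carriers, scores, network), so
adding a stream never perturbs another and identical (config, seed) gives
byte-identical bundles.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real cohorts: linkage disequilibrium and
relatedness (variants and cases are independent), annotation errors
correlated across predictors, frequency-panel ascertainment bias, and any
sequence-level artifacts (reads, alignment, calling).

## Known statistical limitations

Two finite-sample facts about the rare-variant regime (3–13 alternate
alleles per table cell) are measured by the acceptance script rather than
hidden:

* **Wald CI over-coverage.** Empirical 95% CI coverage under the study
  conditions is ≈ 0.99, not 0.95: with cells this small the log-OR
  standard error is dominated by 1/a and 1/c, intervals are very wide,
  and the discrete Wald interval over-covers. The identical code attains
  ≈ 0.958 coverage in a moderate-count regime, confirming the machinery
  is calibrated and the over-coverage is a property of the regime. The
  practical consequence is conservatism: reported CIs are, if anything,
  too wide.
* **Ratio-estimator bias.** The mean of the per-replicate OR estimate
  exceeds the planted OR by a few percent (Jensen's inequality on a/b at
  small a); the quantity that is unbiased is the case allele frequency
  implied by the mean carrier count, and parameter-recovery tests assert
  exactly that, alongside the per-replicate median.

Problem sizes used by the test suite and acceptance script — 1000–2000
synthetic variants or replicate cohorts, 10000 carrier-count replicates
for OR recovery, 500–1000 null cohorts of 50 variants — were chosen as
the smallest sizes at which the Monte-Carlo error bands in the assertions
are meaningfully tight.

## Degenerate inputs and tie-breaks

Zero contingency cells raise unless the Haldane +0.5 correction is
explicitly enabled (never automatic, always flagged, refuses to apply
twice). Empty p-vectors adjust to empty; p-values outside (0, 1] are
rejected. Gene symbols match case-insensitively after whitespace
stripping, with no alias resolution. Population allele counts round
half-up; report percentages are printed both at one decimal and as the
half-up integer of that one-decimal value (54/127 → 42.5% and 43).
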