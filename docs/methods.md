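# Methods

## Scope and data model

The package analyses a cohort of molecular-autopsy (MA) cases.  Each case
carries demographics, a forensic-autopsy (FA) status, an optional death
timestamp, and per-sample annotated variant calls; trios add maternal and
paternal samples.  Annotation (gene symbol, effect class, pathogenicity
category, internal and 1000 Genomes allele frequencies, allelic depths) is
consumed as input: variant calling and the annotation engine that produces
the categories are upstream of this package.  A simplified, configurable
category rule set (`cascade.CategoryRules`) is provided for inputs that
arrive unannotated; when a category annotation is present it is never
overridden.

Two cohort summary tables are packaged as golden fixtures: the 50-case
demographic/autopsy table and the 8-case mtDNA high-burden table.  They
are transcriptions of published summary tables — per-variant exome data
for that cohort were never released, which bounds what can be reproduced
(see *Limitations*).

## Filter cascade

Stages, per sample and in order:

1. **QC** — keep calls whose QC flag passes (VCF `FILTER` of `PASS`/empty).
2. **Internal MAF** — remove calls with internal-database allele frequency
   ≥ 5 % (the boundary is closed on the removal side).
3. **Population MAF** — keep calls with 1000 Genomes frequency < 1 %.

The two boundary conventions are deliberately asymmetric (≥ vs <),
preserving the filter definitions as stated by their authors.  A missing
frequency passes both frequency stages: novel variants are the analysis
target; `strict=True` inverts this for conservative re-analysis.  The
cascade is idempotent and stage counts are monotone non-increasing; both
properties are tested.

Interpretation uses three tiers relative to an SCD gene list: likely
(category 1–2, SCD gene), plausible (category 3, SCD gene), speculative
(category 1–3, gene known in other disorders).  Whether the tiering list
equals the panel used for scope restriction is a user decision; the two
are separate arguments throughout (the synthetic generator exploits this,
see below).  A report is positive iff at least one likely-causal variant
survives.

Count summaries (median, quartiles) use linear interpolation between
order statistics (`numpy.percentile` default), cross-checked in the tests
against a brute-force sort-and-interpolate oracle, since summary tables
rarely state their quartile convention.

## Panel versus exome

Scope restriction is by normalized gene symbol only; a coordinate-overlap
mode is out of scope because panels circulate as symbol lists.  Per-gene
abundance reports total and likely-pathogenic (category 1–2) counts and
their ratio — a crude mutation-tolerance proxy.  Variants without a gene
symbol are excluded from gene-level outputs and counted in an
``unassigned`` bucket.  An optional exclusion regex removes known
histogram-dominating loci (e.g. the protocadherin gamma cluster); it is
off by default.

## Cooccurrence and fingerprint

Gene sharing is counted at the gene level, not the allele level, because
cross-case recurrence of the identical variant is rare at cohort sizes of
tens.  The sharing histogram is cumulative (share ≥ k genes with at least
one other sample); an exact-k mode is provided as the figure convention in
the literature is ambiguous.

The fingerprint collapses categories 1–3 per gene (category 3 inflates
set sizes enough for overlaps to be informative; categories 1–2 alone
give overlaps of ≤ 3 genes).  Jaccard conventions: J = 1 on the diagonal,
J = 0 when the union is empty.  Z-standardization is global over the
strict upper triangle — a single (μ, σ) for all pairs — because a scalar
Z per pair and a global count of pairs above threshold is how such
fingerprints are reported; σ uses the sample convention (ddof = 1),
with ddof = 0 available.  All-equal similarity matrices have no defined
Z and raise rather than returning zeros.

Clustering defaults to complete linkage on Euclidean distances between
rows of the Z matrix, mirroring the defaults of the R heatmap tooling
commonly used for such figures; average/single linkage and a
1 − J distance are configurable.  scipy's agglomerative implementation is
used and is verified in the tests against a naive brute-force
agglomeration oracle on small matrices.

## mtDNA heteroplasmy

HF is defined as the alternate-depth share, d_alt / (d_ref + d_alt) —
summary-level sources rarely print a formula, and this is the standard
read-level definition.  The filtering band is 0.2 < HF < 0.95 with MAF
< 0.05: the lower bound is strict (HF exactly 0.2 is excluded), and the
upper bound, which separates heteroplasmy from effective homoplasmy, is a
package default chosen near the common 0.95 convention and is
configurable.  The packaged rCRS locus map covers the D-loop
(16024–16569 and 1–576, 1-based inclusive) and the major coding/rRNA
loci; unmapped positions (mostly tRNAs) report as `MT-OTHER`.

High burden is ≥ 10 heteroplasmic variants.  Maternal sharing matches
exact (pos, ref, alt) identity; HF similarity is reported but is not a
matching criterion.  The age join classifies infants as strictly under
12 months — the standard "under one year" definition; note that a
1-year-old is *not* an infant even though 12 months is the printed upper
edge of the infant range in summary tables.

## Temporal statistics

Weekday convention is ISO (Monday first).  The clock-window fraction uses
an inclusive start and exclusive end (a death at 08:00 is inside the
default 08:00–20:00 window; one at 20:00 is not).  The day-clustering
p-value is the exact binomial upper tail under uniform weekdays; the
tests verify it against exhaustive enumeration of all 7^n outcomes for
n ≤ 8.  The choice of an exact binomial (rather than chi-square or
permutation) is the package's own: at n = 8 only an exact test is
defensible.

## Synthetic cohort generator

The generator's defaults encode the study conditions the analyses assume:

| parameter | default | rationale |
|---|---|---|
| infant weight | 0.16 | 8 infants / 50 cases |
| adult ages | exp-tilted on (1, 44] y, rate 0.004/month | exponential rise peaking at 30–45 y |
| sex (male) | 0.62 | 1:2 female:male |
| FA positivity | logistic, −4 + 0.012·months | FA− infants, mostly FA+ adults |
| raw calls/sample | Poisson(98 667) | study-scale exome call count |
| stage survivals | 0.815 × 0.058 × 0.076 | per-stage medians; product ≈ 0.36 %, the ~0.4 % retention |
| panel length share | 0.02 | panel captures ~2 % of coding variants |
| panel likely counts | 46/36/12/6 % for 0/1/2/3 | observed per-sample panel histogram |
| MA-positive rate | 0.28 | 14/50 positive reports |
| infant weekday weights | Wed+Thu ≈ 0.87 | midweek infant clustering |
| mtDNA baseline burden | NegBin(r=3, mean 5) | median 4, IQR ≈ 2–7, tail reaching ≥ 10 |
| infant high-burden prob | 0.5 | half of infants high-burden |
| maternal transmission | 1.0 | variants present in mothers |
| HF band | U(0.25, 0.90), ±0.05 maternal jitter | inside the (0.2, 0.95) filter band |

Two modelling points deserve emphasis:

* **28 % vs 54 %.**  The per-sample panel likely-count histogram implies
  54 % of cases carry ≥ 1 likely-pathogenic panel variant, yet only 28 %
  of reports are positive — positivity is an interpretive subset of
  "carries a likely-pathogenic panel variant".  The generator reconciles
  the two by drawing the panel count from the histogram and, conditional
  on carrying any, placing one variant in a *causal-tier* gene subset of
  the panel with probability 0.28/0.54.  Classifying reports against the
  causal list recovers 28 %, while panel-scope counting recovers the
  histogram.  This uses the package's separate-lists design for tiering
  versus scope.
* **Planted calls bypass the frequency filters** (novel, QC-pass), as
  causal variants overwhelmingly do; background panel-gene calls are
  clamped to category ≥ 3 so planted counts are exactly the likely counts.

Stage survivals are drawn independently per variant; real QC failures and
allele frequencies are correlated, so the generator reproduces marginal
stage rates, not their joint structure.  mtDNA positions are drawn
without replacement within a family, so parental sharing counts are exact
set intersections: with transmission probability 0 the expected shared
count is exactly 0 (no background collisions, unlike independent draws).
The infant high-burden *observed* fraction exceeds the planted 0.5
slightly because the baseline negative-binomial tail also crosses 10; the
tests and the acceptance script compare against the analytic expectation
0.5 + 0.5 · P(NB ≥ 10) ≈ 0.56, which also mirrors the real observation
that some non-infants are high-burden.

What the generator does **not** emulate: linkage between variants, site-
and sample-specific coverage structure, annotation errors, population
stratification in allele frequencies, and recurrent (identical) variants
across cases.  Passing recovery tests therefore demonstrates the
pipeline's correctness on data with the assumed marginal structure, not
robustness to real-data artefacts.

## Problem sizes

The default per-sample raw count (≈ 98 667) matches the study scale; the
test suite and the acceptance script run the parameter-recovery cohorts
at reduced per-sample raw counts (250 calls/sample at n = 2000 cases;
3000 at n = 120) — the recovered quantities (survival rates, planted
rates, histograms) are per-variant or per-case rates, independent of the
per-sample scale, and the standard errors quoted in the tests are
computed at the sizes actually run.  mtDNA recovery uses 1000–2000
all-infant cases.

## Numerical and degenerate-input conventions

* Empty variant list: cascade returns zero counts and retention 0.
* Empty gene sets: J = 0 against anything, including another empty set.
* Z-scores: diagonal is NaN (undefined), matrix symmetric.
* `summarize_counts([])`, < 2 samples for J, < 3 for Z, zero total depth
  for HF, nuclear contigs in the mtDNA path: all raise with a message
  rather than returning sentinels.
* Ages normalize to months internally; the sibling-pair case carries both
  probands' ages, contributes its FA-negative sibling to cohort
  statistics and its youngest age to age grouping.
* TSV round trips are exact field-by-field; `repr`-formatted floats avoid
  precision loss.  VCF floats are single precision and are rounded to six
  decimals on ingest.

## Known limitations

* Study-scale quantities that require the unreleased exomes (per-sample
  medians of ~98 667 raw calls, the maximum fingerprint Z of 5.44,
  per-gene exome counts) are not reproduced; the corresponding operations
  are validated structurally against oracles and on synthetic data.
* The demographic percentages sometimes quoted for the San Diego subset
  of the packaged cohort (31 cases) cannot be reconciled exactly with the
  table's race column (which contains `NA` and `Biracial` entries after a
  case-id prefix match of 33); `demographics()` therefore reports raw
  counts and leaves percentage conventions to the caller.
* Gene matching is symbol-based; no liftover, no coordinate overlap.
* The category rule set is a deliberately simple stand-in; it is not an
  attempt to reproduce any proprietary annotation engine, and categories
  4–5 placement of synonymous/noncoding variants is configuration, not
  claim.
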