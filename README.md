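# molautopsy

Cohort-level analysis of **molecular autopsies** — postmortem exome
sequencing of sudden death in the young (SDY, < 45 years).  The package is
aimed at forensic-genetics and cardiogenetics groups who hold per-case
annotated variant tables and want reproducible cohort-level answers to the
questions a medical examiner's sequencing program raises:

* How many calls survive rare-variant filtering, and what does a
  *positive* molecular autopsy mean operationally?
* Does a cardiac gene panel lose diagnostic yield relative to whole exome?
* Do likely pathogenic variants cooccur in the same genes across cases?
* Can a "genetic fingerprint" of affected genes group similar cases?
* Do mitochondrial heteroplasmic variants cluster in infants, and are they
  maternally inherited?

A 50-case SDY cohort summary and its mtDNA high-burden table are packaged
as golden fixtures, and a seeded synthetic-cohort generator emulates the
cohort's statistical structure so every stage is testable without any
sequence download.

## Methods at a glance

**Filter cascade.** Raw calls are reduced per sample by (1) QC pass, (2)
internal-database MAF: discard AF ≥ 5 %, (3) population MAF: keep
AF < 1 % in 1000 Genomes (missing frequency = novel = pass).  Under study
conditions ≈ 0.4 % of raw calls survive.

**Causal tiers.** With pathogenicity categories 1 (reported recognized
cause), 2 (unreported, expected-causal type), 3 (unreported, uncertain
type): *likely* = category 1–2 in a sudden-cardiac-death (SCD) gene,
*plausible* = category 3 in an SCD gene, *speculative* = category 1–3 in a
gene reported for other disorders.  A report is **positive** iff ≥ 1
likely-causal variant is found.

**Genetic fingerprint.** Per sample, the set *G<sub>i</sub>* of genes with
a category 1–3 variant; pairwise Jaccard similarity
*J<sub>ij</sub>* = |G<sub>i</sub> ∩ G<sub>j</sub>| / |G<sub>i</sub> ∪ G<sub>j</sub>|,
standardized over all distinct pairs to
*Z<sub>ij</sub>* = (J<sub>ij</sub> − μ) / σ (sample-sd convention), then
hierarchically clustered (complete linkage, Euclidean row distance).

**mtDNA heteroplasmy.** Heteroplasmic fraction HF = d<sub>alt</sub> /
(d<sub>ref</sub> + d<sub>alt</sub>); variants kept when 0.2 < HF < 0.95
and 1000 Genomes MAF < 0.05; localized against the rCRS map (D-loop =
16024–16569 ∪ 1–576); a sample with ≥ 10 variants is *high-burden*;
maternal sharing = identical (pos, ref, alt) in the mother's profile.

**Temporal clustering.** Exact binomial upper tail for k of n deaths on d
of 7 equiprobable weekdays: p = Σ<sub>i≥k</sub> C(n,i) (d/7)<sup>i</sup>
(1 − d/7)<sup>n−i</sup>.

## Worked example

```python
from molautopsy import stats
from molautopsy.io import load_cohort_cases

cases = load_cohort_cases()           # packaged 50-case cohort
t = stats.yield_table(cases)
print(t.n_pp, t.n_pn, t.n_np, t.n_nn) # -> 9 5 17 19
d = t.as_dict()
print(d["pct_ma_positive"], d["pct_fa_positive"])  # -> 28.0 52.0

groups = stats.age_groups(cases)
print({k: len(v) for k, v in groups.items()})
# -> {'infants': 8, 'minors': 17, 'full': 50}

test = stats.binomial_day_cluster_test(k=7, n=8, d=2)
print(round(test.p_value, 7))         # -> 0.0009326
```

Reading: of 50 cases, 14 (28 %) had a positive molecular autopsy and 26
(52 %) a positive forensic autopsy; in 19 cases (38 %) both came back
negative, so the combined yield of the two examinations is what drives
the diagnosis rate.  Seven of the eight infant deaths falling on just two
weekdays would occur by chance with probability ≈ 9.3 × 10⁻⁴.

The same numbers are available from the shell:

```bash
ma cohort-report --cases "$(python -c 'from molautopsy.io import fixture_path; print(fixture_path("table1_cases"))')"
```

Other subcommands (`ma simulate`, `ma filter`, `ma panel-compare`,
`ma cooccur`, `ma fingerprint`, `ma mtdna`) wrap the corresponding library
modules; every run writes a JSON report echoing its thresholds.

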