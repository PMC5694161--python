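"""Variant reduction cascade and causal-tier interpretation.

Raw per-sample variant calls are reduced in three stages:

1. QC: keep calls flagged as passing quality control;
2. internal-database frequency: discard common variants, i.e. allele
   frequency >= 5% in the internal cohort database (``af >= cut`` removed,
   matching the study's printed ">=5%" boundary);
3. population frequency: keep variants with 1000 Genomes allele frequency
   < 1% ("<1%" boundary kept asymmetric on purpose).

A missing frequency is treated as rare and passes (novel variants are the
analysis target); ``strict=True`` makes a missing frequency fail instead.
The cascade retains roughly 0.4% of raw calls under study conditions.

Surviving variants are interpreted in three tiers relative to a list of
sudden-cardiac-death (SCD) genes: *likely* causal (pathogenicity category
1-2 in an SCD gene), *plausibly* causal (category 3, i.e. a variant of
unknown significance, in an SCD gene) and *speculative* (category 1-3 in a
gene reported for other disorders).  A molecular-autopsy report is positive
iff at least one variant is likely causal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import PanelDefinition, VariantRecord, normalize_gene

logger = logging.getLogger(__name__)

TIERS = ("likely", "plausible", "speculative", "none")


@dataclass(slots=True)
class CascadeReport:
    """Per-stage survivor counts for one sample's cascade run."""

    sample_id: str
    n_raw: int
    n_qc: int
    n_internal: int
    n_final: int

    def __post_init__(self) -> None:
        if not self.n_raw >= self.n_qc >= self.n_internal >= self.n_final >= 0:
            raise ValueError(f"stage counts must be non-increasing: {self}")

    @property
    def retained_fraction(self) -> float:
        """n_final / n_raw; 0 for an empty input by convention."""
        return self.n_final / self.n_raw if self.n_raw else 0.0


def apply_cascade(
    variants: list[VariantRecord],
    internal_maf_cut: float = 0.05,
    kg_maf_cut: float = 0.01,
    strict: bool = False,
) -> tuple[list[VariantRecord], CascadeReport]:
    """Run the three filtering stages on one sample's variants.

    Returns the survivors (input order preserved) and a
    :class:`CascadeReport` with the per-stage counts.  Mixed sample ids are
    fatal: the cascade is defined per sample.
    """
    sample_ids = {v.sample_id for v in variants}
    if len(sample_ids) > 1:
        raise ValueError(f"apply_cascade expects one sample, got {sorted(sample_ids)}")
    sample_id = next(iter(sample_ids)) if sample_ids else ""

    def freq_pass(af: float | None, cut: float) -> bool:
        if af is None:
            return not strict
        return af < cut

    after_qc = [v for v in variants if v.qc_pass]
    after_internal = [v for v in after_qc if freq_pass(v.af_internal, internal_maf_cut)]
    after_kg = [v for v in after_internal if freq_pass(v.af_1kg, kg_maf_cut)]
    report = CascadeReport(
        sample_id=sample_id,
        n_raw=len(variants),
        n_qc=len(after_qc),
        n_internal=len(after_internal),
        n_final=len(after_kg),
    )
    return after_kg, report


def apply_cascade_cohort(
    variants: list[VariantRecord], **kwargs
) -> tuple[list[VariantRecord], dict[str, CascadeReport]]:
    """Run the cascade per sample over a pooled cohort table."""
    by_sample: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    survivors: list[VariantRecord] = []
    reports: dict[str, CascadeReport] = {}
    for sample_id, recs in by_sample.items():
        kept, report = apply_cascade(recs, **kwargs)
        survivors.extend(kept)
        reports[sample_id] = report
    return survivors, reports


@dataclass
class CategoryRules:
    """Configurable stand-in for the external annotation engine.

    ``known_pathogenic`` holds (gene, cDNA change) pairs of reported causal
    variants (category 1).  Unreported variants fall to category 2 when
    their effect class is expected-causal (nonsense/frameshift/splice),
    category 3 for missense, and to ``effect_defaults`` otherwise.  Used
    only when the input carries no category annotation.
    """

    known_pathogenic: set[tuple[str, str]] = field(default_factory=set)
    expected_causal_effects: frozenset[str] = frozenset({"nonsense", "frameshift", "splice"})
    effect_defaults: dict[str, int] = field(
        default_factory=lambda: {"synonymous": 4, "noncoding": 5, "other": 5}
    )
    fallback_category: int = 5

    def lookup_key(self, variant: VariantRecord) -> tuple[str, str] | None:
        if variant.gene is None:
            return None
        change = variant.hgvs_c or f"g.{variant.pos}{variant.ref_allele}>{variant.alt_allele}"
        return (normalize_gene(variant.gene), change)


def assign_category(variant: VariantRecord, rules: CategoryRules) -> int:
    """Assign a pathogenicity category 1-5 from the rule config.

    Never call this on a variant that already carries a category; existing
    annotations are authoritative (see :func:`ensure_categories`).
    """
    key = rules.lookup_key(variant)
    if key is not None and key in rules.known_pathogenic:
        return 1
    if variant.effect_class in rules.expected_causal_effects:
        return 2
    if variant.effect_class == "missense":
        return 3
    cat = rules.effect_defaults.get(variant.effect_class)
    if cat is None:
        logger.warning(
            "no category rule for effect class %r; using fallback %d",
            variant.effect_class,
            rules.fallback_category,
        )
        cat = rules.fallback_category
    return cat


def ensure_categories(variants: list[VariantRecord], rules: CategoryRules) -> list[VariantRecord]:
    """Fill in missing categories in place; annotated inputs are untouched."""
    for v in variants:
        if v.category is None:
            v.category = assign_category(v, rules)
    return variants


def assign_tier(
    variant: VariantRecord,
    scd_genes: PanelDefinition,
    other_disease_genes: PanelDefinition | None = None,
) -> str:
    """Causal tier of one categorized variant.

    likely: category 1-2 in an SCD gene; plausible: category 3 in an SCD
    gene; speculative: category 1-3 in a gene from the other-disorders
    lookup; none otherwise.
    """
    if variant.category is None:
        raise ValueError(f"variant at {variant.chrom}:{variant.pos} has no category")
    in_scd = variant.gene in scd_genes
    if variant.category in (1, 2) and in_scd:
        return "likely"
    if variant.category == 3 and in_scd:
        return "plausible"
    if variant.category in (1, 2, 3) and not in_scd and other_disease_genes is not None:
        if variant.gene in other_disease_genes:
            return "speculative"
    return "none"


def classify_report(
    variants: list[VariantRecord],
    scd_genes: PanelDefinition,
    other_disease_genes: PanelDefinition | None = None,
) -> str:
    """Positive iff >= 1 variant is likely causal, else negative."""
    for v in variants:
        if assign_tier(v, scd_genes, other_disease_genes) == "likely":
            return "positive"
    return "negative"


def summarize_counts(values: list[float]) -> dict[str, float]:
    """Median/quartiles/min/max of per-sample counts.

    Quartiles use linear interpolation between order statistics (the
    default of :func:`numpy.percentile`).
    """
    if len(values) == 0:
        raise ValueError("summarize_counts requires a non-empty list")
    arr = np.asarray(values, dtype=float)
    return {
        "median": float(np.median(arr)),
        "q1": float(np.percentile(arr, 25)),
        "q3": float(np.percentile(arr, 75)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }
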