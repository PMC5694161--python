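"""Cross-sample sharing of genes carrying likely pathogenic variants.

For each sample, the set of genes with at least one category-1/2 variant
is compared against every other sample; ``max_shared`` is the largest
overlap with any single other sample.  The cohort histogram reports, for
k = 1..k_max, the percentage of samples sharing at least k genes with at
least one other sample (cumulative, the default reading of the study's
"shared up to three genes" figure; an exact-k mode is also provided).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import VariantRecord, normalize_gene
from .panel import LIKELY_CATEGORIES


@dataclass(slots=True)
class SharingProfile:
    sample_id: str
    genes_likely: frozenset[str]
    max_shared: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.max_shared <= len(self.genes_likely):
            raise ValueError(f"max_shared out of range for {self.sample_id}")


def likely_gene_sets(variants: list[VariantRecord]) -> dict[str, set[str]]:
    """Per sample, genes carrying >= 1 likely pathogenic (cat 1-2) variant."""
    sets: dict[str, set[str]] = {}
    for v in variants:
        sets.setdefault(v.sample_id, set())
        if v.category in LIKELY_CATEGORIES and v.gene is not None:
            sets[v.sample_id].add(normalize_gene(v.gene))
    return sets


def build_sharing_profiles(variants: list[VariantRecord]) -> list[SharingProfile]:
    """Pairwise max gene-set overlap per sample; needs >= 2 samples."""
    sets = likely_gene_sets(variants)
    if len(sets) < 2:
        raise ValueError("sharing analysis requires at least two samples")
    sample_ids = sorted(sets)
    profiles = []
    for s in sample_ids:
        best = max(len(sets[s] & sets[t]) for t in sample_ids if t != s)
        profiles.append(SharingProfile(sample_id=s, genes_likely=frozenset(sets[s]), max_shared=best))
    return profiles


def sharing_histogram(
    profiles: list[SharingProfile], k_max: int = 3, mode: str = "cumulative"
) -> dict[int, float]:
    """Percent of samples with max_shared >= k (or == k for mode='exact')."""
    if not profiles:
        raise ValueError("sharing_histogram requires at least one profile")
    if mode not in ("cumulative", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(profiles)
    out = {}
    for k in range(1, k_max + 1):
        if mode == "cumulative":
            hits = sum(1 for p in profiles if p.max_shared >= k)
        else:
            hits = sum(1 for p in profiles if p.max_shared == k)
        out[k] = 100.0 * hits / n
    return out


def gene_sharing_counts(variants: list[VariantRecord]) -> dict[str, int]:
    """Per gene, the number of distinct samples carrying a likely variant.

    A sample with two likely variants in the same gene counts once; genes
    with no likely variant are absent from the output.
    """
    carriers: dict[str, set[str]] = {}
    for v in variants:
        if v.category in LIKELY_CATEGORIES and v.gene is not None:
            carriers.setdefault(normalize_gene(v.gene), set()).add(v.sample_id)
    return {g: len(s) for g, s in sorted(carriers.items())}
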