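"""Gene-panel restriction and the exome-vs-panel comparison.

The study asks whether "de-escalating" from whole exome to a cardiac gene
panel loses diagnostic yield.  These helpers restrict a variant list to a
panel, tabulate per-gene abundance and likely-pathogenic ratios, count
likely-pathogenic variants per sample in either scope, and tally effect
classes.  "Likely pathogenic" throughout means pathogenicity category 1
(reported recognized cause) or 2 (unreported, expected-causal type).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io import PanelDefinition, VariantRecord, normalize_gene

LIKELY_CATEGORIES = frozenset({1, 2})


@dataclass(slots=True)
class GeneAbundance:
    """Cohort-wide variant counts for one gene."""

    gene: str
    n_total: int
    n_likely: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_likely <= self.n_total:
            raise ValueError(f"need 0 <= n_likely <= n_total, got {self}")

    @property
    def ratio(self) -> float:
        """Likely-pathogenic share of the gene's variants (tolerance proxy)."""
        return self.n_likely / self.n_total if self.n_total else 0.0


def restrict_to_panel(variants: list[VariantRecord], panel: PanelDefinition) -> list[VariantRecord]:
    """Keep exactly the variants whose gene is in the panel, order preserved."""
    return [v for v in variants if v.gene in panel]


def gene_abundance(
    variants: list[VariantRecord],
    min_likely: int = 0,
    exclude_pattern: str | None = None,
) -> tuple[list[GeneAbundance], int]:
    """Per-gene variant counts pooled across the cohort.

    Returns (rows, n_unassigned): one row per gene with >= 1 variant,
    restricted to genes with >= ``min_likely`` likely-pathogenic variants
    when the threshold is positive, sorted by total count descending with
    alphabetical tie-break; ``n_unassigned`` counts variants without a gene
    symbol.  ``exclude_pattern`` drops matching symbols (e.g. the
    protocadherin-cluster loci, which a histogram would otherwise be
    dominated by); off by default.
    """
    regex = re.compile(exclude_pattern) if exclude_pattern else None
    totals: dict[str, int] = {}
    likely: dict[str, int] = {}
    unassigned = 0
    for v in variants:
        if v.gene is None:
            unassigned += 1
            continue
        g = normalize_gene(v.gene)
        if regex is not None and regex.fullmatch(g):
            continue
        totals[g] = totals.get(g, 0) + 1
        if v.category in LIKELY_CATEGORIES:
            likely[g] = likely.get(g, 0) + 1
    rows = [
        GeneAbundance(gene=g, n_total=n, n_likely=likely.get(g, 0))
        for g, n in totals.items()
        if likely.get(g, 0) >= min_likely
    ]
    rows.sort(key=lambda r: (-r.n_total, r.gene))
    return rows, unassigned


def per_sample_likely_counts(
    variants: list[VariantRecord],
    scope: str = "exome",
    panel: PanelDefinition | None = None,
    sample_ids: list[str] | None = None,
) -> dict[str, int]:
    """Likely-pathogenic variants per sample, in exome or panel scope.

    Every cohort sample appears in the mapping, including zero-count ones;
    pass ``sample_ids`` to include samples with no variants at all.
    """
    if scope not in ("exome", "panel"):
        raise ValueError(f"scope must be 'exome' or 'panel', got {scope!r}")
    if scope == "panel" and panel is None:
        raise ValueError("panel scope requires a PanelDefinition")
    counts: dict[str, int] = dict.fromkeys(sample_ids or (), 0)
    for v in variants:
        counts.setdefault(v.sample_id, 0)
        if v.category in LIKELY_CATEGORIES and (scope == "exome" or v.gene in panel):
            counts[v.sample_id] += 1
    return counts


def likely_count_histogram(counts: dict[str, int]) -> dict[int, int]:
    """Histogram of per-sample likely counts: k -> number of samples."""
    hist: dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    return dict(sorted(hist.items()))


def effect_class_tally(variants: list[VariantRecord]) -> dict[str, int]:
    """Effect-class counts among likely-pathogenic variants (zeros kept)."""
    from .io import EFFECT_CLASSES

    tally = dict.fromkeys(EFFECT_CLASSES, 0)
    for v in variants:
        if v.category in LIKELY_CATEGORIES:
            tally[v.effect_class] += 1
    return tally
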