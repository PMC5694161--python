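"""Mitochondrial heteroplasmy quantification and maternal sharing.

The heteroplasmic fraction (HF) of a mitochondrial call is the
alternate-allele share of reads, ``depth_alt / (depth_ref + depth_alt)``.
A variant counts as heteroplasmic when ``hf_low < HF < hf_high`` (default
band 0.2-0.95: the lower bound reproduces the study's strict ">0.2"
filter, the upper bound separates heteroplasmy from homoplasmy) and its
1000 Genomes allele frequency is < 0.05 (missing frequency passes).
Variants are localized against an rCRS locus map; the D-loop control
region spans positions 16024-16569 and 1-576 (1-based inclusive).  A
sample carrying >= 10 heteroplasmic variants is flagged high-burden.

Maternal sharing counts proband variants whose (pos, ref, alt) identity
is also present in the mother's filtered profile; HF closeness is not a
matching criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats as _stats

from .io import CaseRecord, VariantRecord, fixture_path

HIGH_BURDEN_MIN = 10  # variants; >= 10 flags a high-burden sample


@dataclass(slots=True)
class MtVariant:
    pos: int
    ref: str
    alt: str
    hf: float
    locus: str

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


@dataclass
class HeteroplasmyProfile:
    """Filtered heteroplasmic variants and burden summary for one sample."""

    sample_id: str
    variants: list[MtVariant] = field(default_factory=list)
    shared_with_mother: int | None = None
    shared_with_father: int | None = None

    @property
    def n_total(self) -> int:
        return len(self.variants)

    @property
    def n_dloop(self) -> int:
        return sum(1 for v in self.variants if v.locus == "MT-DLOOP")

    @property
    def high_burden(self) -> bool:
        return self.n_total >= HIGH_BURDEN_MIN

    @property
    def keys(self) -> set[tuple[int, str, str]]:
        return {v.key for v in self.variants}


class MtLocusMap:
    """Named intervals on the mitochondrial reference (1-based inclusive)."""

    MT_LENGTH = 16569

    def __init__(self, intervals: list[tuple[str, int, int]]):
        if not intervals:
            raise ValueError("locus map needs at least one interval")
        for name, start, end in intervals:
            if not (1 <= start <= end <= self.MT_LENGTH):
                raise ValueError(f"interval {name} {start}-{end} outside mitochondrial genome")
        by_locus: dict[str, list[tuple[int, int]]] = {}
        for name, start, end in intervals:
            for s, e in by_locus.get(name, ()):
                if start <= e and s <= end:
                    raise ValueError(f"overlapping intervals within locus {name}")
            by_locus.setdefault(name, []).append((start, end))
        self.intervals = list(intervals)

    @classmethod
    def from_file(cls, path: str | Path) -> "MtLocusMap":
        df = pd.read_csv(path, sep="\t")
        return cls([(r.locus, int(r.start), int(r.end)) for r in df.itertuples(index=False)])

    @classmethod
    def default(cls) -> "MtLocusMap":
        """Packaged rCRS map: D-loop plus the major coding/rRNA loci."""
        return cls.from_file(fixture_path("rcrs_loci"))

    def locus_of(self, pos: int) -> str:
        """First matching locus name, or 'MT-OTHER' (tRNAs, spacers)."""
        for name, start, end in self.intervals:
            if start <= pos <= end:
                return name
        return "MT-OTHER"


def heteroplasmic_fraction(depth_ref: int, depth_alt: int) -> float:
    """Alternate-depth share of reads; zero total depth is an error."""
    total = depth_ref + depth_alt
    if total <= 0:
        raise ValueError("heteroplasmic fraction undefined at zero total depth")
    return depth_alt / total


def filter_heteroplasmic(
    variants: list[VariantRecord],
    hf_low: float = 0.2,
    hf_high: float = 0.95,
    maf_cut: float = 0.05,
    locus_map: MtLocusMap | None = None,
) -> HeteroplasmyProfile:
    """Heteroplasmic profile of one sample's mitochondrial records.

    Keeps variants with hf_low < HF < hf_high (both bounds strict; HF
    exactly at the lower bound is excluded) and population MAF < maf_cut
    (missing passes).  Nuclear records in the input are fatal.
    """
    if locus_map is None:
        locus_map = MtLocusMap.default()
    sample_ids = {v.sample_id for v in variants}
    if len(sample_ids) > 1:
        raise ValueError(f"expected one sample, got {sorted(sample_ids)}")
    kept: list[MtVariant] = []
    for v in variants:
        if not v.is_mitochondrial:
            raise ValueError(f"nuclear record {v.chrom}:{v.pos} in mitochondrial analysis")
        if v.depth_ref is None or v.depth_alt is None:
            raise ValueError(f"mtDNA record at {v.pos} lacks allele depths")
        hf = heteroplasmic_fraction(v.depth_ref, v.depth_alt)
        if not (hf_low < hf < hf_high):
            continue
        if v.af_1kg is not None and v.af_1kg >= maf_cut:
            continue
        kept.append(
            MtVariant(pos=v.pos, ref=v.ref_allele, alt=v.alt_allele, hf=hf, locus=locus_map.locus_of(v.pos))
        )
    sample_id = next(iter(sample_ids)) if sample_ids else ""
    return HeteroplasmyProfile(sample_id=sample_id, variants=kept)


def maternal_sharing(
    proband: HeteroplasmyProfile,
    mother: HeteroplasmyProfile | None,
    father: HeteroplasmyProfile | None = None,
) -> HeteroplasmyProfile:
    """Count proband variants identically present in each parent's profile.

    Identity is exact (pos, ref, alt); counts are recorded on the returned
    proband profile, independently for mother and father, and stay missing
    for an unsequenced parent.
    """
    if mother is not None:
        proband.shared_with_mother = len(proband.keys & mother.keys)
    if father is not None:
        proband.shared_with_father = len(proband.keys & father.keys)
    return proband


def burden_vs_age(
    profiles: list[HeteroplasmyProfile],
    cases: list[CaseRecord],
    sample_to_case: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Join per-sample heteroplasmy burden to case age and autopsy status.

    Returns one row per joinable profile (case_id, age_months, n_total,
    n_dloop, high_burden, is_infant, fa_status); unjoinable samples are
    warned about and excluded.  Infant = age under 12 months.
    """
    import logging

    by_case = {c.case_id: c for c in cases}
    rows = []
    for p in profiles:
        case_id = (sample_to_case or {}).get(p.sample_id, p.sample_id)
        case = by_case.get(case_id)
        if case is None:
            logging.getLogger(__name__).warning("sample %s joins no case; excluded", p.sample_id)
            continue
        rows.append(
            {
                "case_id": case.case_id,
                "age_months": case.age_months,
                "n_total": p.n_total,
                "n_dloop": p.n_dloop,
                "high_burden": p.high_burden,
                "is_infant": case.age_months < 12.0,
                "fa_status": case.fa_status,
            }
        )
    return pd.DataFrame(rows, columns=["case_id", "age_months", "n_total", "n_dloop", "high_burden", "is_infant", "fa_status"])


def high_burden_summary(table: pd.DataFrame) -> dict[str, int]:
    """Counts of high-burden samples and infants among them."""
    hb = table[table["high_burden"]]
    return {
        "n_high_burden": int(len(hb)),
        "n_high_burden_infants": int(hb["is_infant"].sum()),
    }


def profiles_from_burden_counts(counts: pd.DataFrame) -> list[HeteroplasmyProfile]:
    """Profiles carrying only burden counts (no per-variant detail).

    Supports summary inputs such as the packaged high-burden table, whose
    per-variant lists were never published: each profile gets ``n_total``
    placeholder variants so burden-level analyses (counts, high-burden
    flag, age join) work unchanged.  D-loop membership is encoded on the
    first ``proband_dloop`` placeholders.
    """
    profiles = []
    for r in counts.itertuples(index=False):
        n_total = int(r.proband_all)
        n_dloop = int(r.proband_dloop)
        variants = [
            MtVariant(pos=i + 1, ref="N", alt="A", hf=0.5, locus="MT-DLOOP" if i < n_dloop else "MT-OTHER")
            for i in range(n_total)
        ]
        p = HeteroplasmyProfile(sample_id=r.case_id, variants=variants)
        if not pd.isna(getattr(r, "mother_shared_all", float("nan"))):
            p.shared_with_mother = int(r.mother_shared_all)
        if not pd.isna(getattr(r, "father_shared_all", float("nan"))):
            p.shared_with_father = int(r.father_shared_all)
        profiles.append(p)
    return profiles


def coverage_association(profiles: list[HeteroplasmyProfile], mean_depths: dict[str, float]) -> dict[str, float]:
    """Optional diagnostic: Spearman correlation of burden vs mean depth."""
    pairs = [(p.n_total, mean_depths[p.sample_id]) for p in profiles if p.sample_id in mean_depths]
    if len(pairs) < 3:
        raise ValueError("need at least three samples with depth information")
    burden, depth = zip(*pairs)
    rho, pval = _stats.spearmanr(burden, depth)
    return {"spearman_rho": float(rho), "p_value": float(pval)}
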