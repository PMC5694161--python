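"""Seeded synthetic molecular-autopsy cohorts.

The generator emulates the statistical structure the cohort analysis
assumes, so that every pipeline stage is testable without access to the
(unreleased) study exomes:

* a bimodal age distribution — an infant peak (weight 8/50) plus an
  exponential increase toward 44 years;
* a 1:2 female:male ratio;
* forensic-autopsy positivity increasing with age (logistic in months);
* per-gene variant counts proportional to coding length, over a synthetic
  gene catalog with a long-tailed length distribution and named anchor
  genes (TTN-like, MUC16-like), a ~20-gene cardiac panel holding ~2% of
  total coding length, and a causal-tier subset of the panel;
* an allele-frequency/QC mixture tuned so the filter cascade retains
  roughly 0.4% of raw calls (stage survivals 0.815 x 0.058 x 0.076);
* per-sample panel likely-pathogenic counts following the 46/36/12/6%
  histogram, with a 28% rate of cases carrying a causal-tier (molecular
  autopsy positive) variant — the causal genes are a strict subset of the
  panel, which is what lets both rates hold at once;
* death timestamps with weekday/hour/month structure (midweek-heavy for
  infants, Monday-peaked for adults, daytime-heavy hours, April peak);
* maternally transmitted mtDNA heteroplasmy, with half of infants drawn
  from a high-burden (>= 10 variants) component.

All draws flow from ``numpy.random.default_rng`` seeded from
``GeneratorConfig.seed``; each generator uses an independent child stream
so outputs do not depend on call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .io import (
    CaseRecord,
    PanelDefinition,
    PedigreeLink,
    VariantRecord,
    write_case_table,
    write_panel,
    write_pedigree,
    write_variant_table,
)

_BASES = ("A", "C", "G", "T")

_DLOOP_POSITIONS = np.concatenate([np.arange(1, 577), np.arange(16024, 16570)])
_NON_DLOOP_POSITIONS = np.arange(577, 16024)


@dataclass(slots=True)
class GeneInfo:
    symbol: str
    chrom: str
    start: int
    length_kb: float
    in_panel: bool = False
    causal: bool = False


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_cases: int = 50
    seed: int = 0

    # demographics
    infant_weight: float = 0.16  # 8/50
    infant_age_months: tuple[int, int] = (1, 11)  # uniform, inclusive
    adult_age_months: tuple[float, float] = (12.0, 528.0)
    adult_age_rate: float = 0.004  # exponential tilt per month, increasing
    sex_male_prob: float = 0.62  # 31/50

    # forensic autopsy positivity, logistic in age (months)
    fa_intercept: float = -4.0
    fa_slope_per_month: float = 0.012

    # nuclear variants
    mean_raw_variants: float = 98667.0
    stage_survival: tuple[float, float, float] = (0.815, 0.058, 0.076)
    af_missing_prob: float = 0.3  # rare variants with no database frequency
    background_effect_probs: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.50,
            "synonymous": 0.25,
            "noncoding": 0.15,
            "splice": 0.03,
            "nonsense": 0.02,
            "frameshift": 0.02,
            "other": 0.03,
        }
    )
    # background category distribution per effect class (panel genes are
    # clamped to >= 3 so likely-pathogenic panel counts stay planted-only)
    category_probs: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "missense": {3: 0.85, 4: 0.15},
            "nonsense": {2: 0.45, 3: 0.35, 4: 0.20},
            "frameshift": {2: 0.45, 3: 0.35, 4: 0.20},
            "splice": {2: 0.45, 3: 0.35, 4: 0.20},
            "synonymous": {4: 0.9, 5: 0.1},
            "noncoding": {5: 1.0},
            "other": {5: 1.0},
        }
    )

    # planted likely-pathogenic panel variants
    ma_likely_rate: float = 0.28
    panel_likely_count_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.46, 1: 0.36, 2: 0.12, 3: 0.06}
    )
    likely_effect_probs: dict[str, float] = field(
        default_factory=lambda: {"missense": 0.75, "nonsense": 0.10, "frameshift": 0.15}
    )

    # gene catalog
    n_genes: int = 200
    n_panel_genes: int = 20
    n_causal_genes: int = 8
    panel_length_share: float = 0.02
    gene_length_sigma: float = 1.0  # lognormal sigma of lengths

    # death timestamps
    study_start: datetime = datetime(2014, 8, 1)
    study_years: tuple[int, ...] = (2014, 2015, 2016, 2017)
    infant_weekday_weights: tuple[float, ...] = (0.03, 0.03, 0.45, 0.42, 0.01, 0.03, 0.03)
    weekday_weights: tuple[float, ...] = (0.22, 0.15, 0.13, 0.13, 0.08, 0.14, 0.15)
    hour_weights: tuple[float, ...] = tuple([0.5] * 8 + [1.5] * 12 + [0.5] * 4)
    month_weights: tuple[float, ...] = (0.06, 0.07, 0.08, 0.14, 0.03, 0.10, 0.07, 0.07, 0.10, 0.11, 0.09, 0.08)

    # mtDNA heteroplasmy
    mt_baseline_r: float = 3.0  # negative-binomial shape of baseline burden
    mt_baseline_mean: float = 5.0
    high_burden_infant_prob: float = 0.5
    high_burden_min: int = 10
    high_burden_extra_mean: float = 2.5
    maternal_transmission_prob: float = 1.0
    hf_band: tuple[float, float] = (0.25, 0.90)
    hf_noise: float = 0.05
    dloop_prob: float = 0.4
    mt_depth_mean: float = 500.0
    mother_background_mean: float = 3.0
    father_background_mean: float = 2.0
    trio_prob_minor: float = 0.9
    trio_prob_adult: float = 0.1

    def validate(self) -> None:
        probs = {
            "infant_weight": self.infant_weight,
            "sex_male_prob": self.sex_male_prob,
            "ma_likely_rate": self.ma_likely_rate,
            "high_burden_infant_prob": self.high_burden_infant_prob,
            "maternal_transmission_prob": self.maternal_transmission_prob,
            "dloop_prob": self.dloop_prob,
            "panel_length_share": self.panel_length_share,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        for name in ("stage_survival",):
            if any(not 0.0 <= s <= 1.0 for s in getattr(self, name)):
                raise ValueError(f"{name} entries must be in [0,1]")
        for name in ("weekday_weights", "infant_weekday_weights", "hour_weights", "month_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if (w < 0).any() or w.sum() == 0:
                raise ValueError(f"{name} must be nonnegative and not all zero")
        hist = self.panel_likely_count_probs
        if abs(sum(hist.values()) - 1.0) > 1e-9:
            raise ValueError("panel_likely_count_probs must sum to 1")
        p_any = 1.0 - hist.get(0, 0.0)
        if self.ma_likely_rate > p_any + 1e-12:
            raise ValueError(
                "ma_likely_rate cannot exceed the probability of carrying "
                f"any panel likely variant ({p_any})"
            )
        if not 0 < self.n_causal_genes < self.n_panel_genes < self.n_genes:
            raise ValueError("need n_causal_genes < n_panel_genes < n_genes")

    @property
    def expected_background_retention(self) -> float:
        s1, s2, s3 = self.stage_survival
        return s1 * s2 * s3

    @property
    def expected_panel_likely_mean(self) -> float:
        return sum(k * p for k, p in self.panel_likely_count_probs.items())

    def _rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), sum(map(ord, stream))])


# ---------------------------------------------------------------------------
# gene catalog


def build_gene_catalog(config: GeneratorConfig) -> list[GeneInfo]:
    """Synthetic gene catalog with anchors and a fixed panel length share.

    Lengths (kb) are lognormal with real-scale anchors (TTN 305 kb, MUC16
    132 kb, SSPO 58 kb); panel-gene lengths are rescaled so the panel holds
    ``panel_length_share`` of total coding length, which sets the expected
    panel share of background variants.
    """
    rng = config._rng("genes")
    n = config.n_genes
    lengths = np.exp(rng.normal(np.log(20.0), config.gene_length_sigma, size=n))
    symbols = [f"SYG{i:03d}" for i in range(n)]
    # anchors: TTN in the panel, MUC16/SSPO outside it
    symbols[0], lengths[0] = "TTN", 305.0
    symbols[1], lengths[1] = "MUC16", 132.0
    symbols[2], lengths[2] = "SSPO", 58.0
    panel_idx = [0] + list(range(3, 2 + config.n_panel_genes))
    panel_mask = np.zeros(n, dtype=bool)
    panel_mask[panel_idx] = True
    target = config.panel_length_share
    scale = (target / (1 - target)) * lengths[~panel_mask].sum() / lengths[panel_mask].sum()
    lengths[panel_mask] *= scale
    causal_idx = panel_idx[1 : 1 + config.n_causal_genes]  # TTN stays non-causal
    causal_mask = np.zeros(n, dtype=bool)
    causal_mask[causal_idx] = True
    genes = []
    pos_cursor = {}
    for i in range(n):
        chrom = str(i % 22 + 1)
        start = pos_cursor.get(chrom, 1_000_000)
        pos_cursor[chrom] = start + int(lengths[i] * 1000) + 100_000
        genes.append(
            GeneInfo(
                symbol=symbols[i],
                chrom=chrom,
                start=start,
                length_kb=float(lengths[i]),
                in_panel=bool(panel_mask[i]),
                causal=bool(causal_mask[i]),
            )
        )
    return genes


def panel_of(genes: list[GeneInfo], name: str = "panel") -> PanelDefinition:
    return PanelDefinition(name=name, genes=frozenset(g.symbol for g in genes if g.in_panel))


def causal_panel_of(genes: list[GeneInfo], name: str = "causal") -> PanelDefinition:
    return PanelDefinition(name=name, genes=frozenset(g.symbol for g in genes if g.causal))


# ---------------------------------------------------------------------------
# cases


def _draw_timestamp(rng: np.random.Generator, config: GeneratorConfig, weekday_weights) -> datetime:
    month_w = np.asarray(config.month_weights, dtype=float)
    day_w = np.asarray(weekday_weights, dtype=float)
    hour_w = np.asarray(config.hour_weights, dtype=float)
    year = int(rng.choice(config.study_years))
    month = int(rng.choice(12, p=month_w / month_w.sum())) + 1
    weekday = int(rng.choice(7, p=day_w / day_w.sum()))
    # days of this month falling on the drawn weekday
    first = datetime(year, month, 1)
    days = []
    d = first
    while d.month == month:
        if d.weekday() == weekday:
            days.append(d)
        d += timedelta(days=1)
    day = days[int(rng.integers(len(days)))]
    hour = int(rng.choice(24, p=hour_w / hour_w.sum()))
    minute = int(rng.integers(60))
    return day.replace(hour=hour, minute=minute)


def generate_cases(config: GeneratorConfig) -> list[CaseRecord]:
    """Draw demographics, forensic-autopsy status and death timestamps."""
    config.validate()
    rng = config._rng("cases")
    cases = []
    lo, hi = config.adult_age_months
    r = config.adult_age_rate
    for i in range(config.n_cases):
        case_id = f"SY{i:05d}"
        if rng.random() < config.infant_weight:
            a, b = config.infant_age_months
            age_value = float(rng.integers(a, b + 1))
            age_unit = "months"
            weekday_weights = config.infant_weekday_weights
        else:
            u = rng.random()
            age_m = np.log(np.exp(r * lo) + u * (np.exp(r * hi) - np.exp(r * lo))) / r
            age_value = round(age_m / 12.0, 1)
            age_unit = "years"
            weekday_weights = config.weekday_weights
        age_months = age_value if age_unit == "months" else age_value * 12.0
        sex = "male" if rng.random() < config.sex_male_prob else "female"
        p_fa = 1.0 / (1.0 + np.exp(-(config.fa_intercept + config.fa_slope_per_month * age_months)))
        fa_status = "positive" if rng.random() < p_fa else "negative"
        cases.append(
            CaseRecord(
                case_id=case_id,
                age_value=age_value,
                age_unit=age_unit,
                sex=sex,
                fa_status=fa_status,
                fa_summary="synthetic",
                death_time=_draw_timestamp(rng, config, weekday_weights),
                site_label="SY00",
            )
        )
    return cases


def generate_pedigree(cases: list[CaseRecord], config: GeneratorConfig) -> list[PedigreeLink]:
    """Trio availability: common for minors, rare for adults."""
    rng = config._rng("pedigree")
    links = []
    for c in cases:
        p_trio = config.trio_prob_minor if c.age_months <= 216.0 else config.trio_prob_adult
        has_parents = rng.random() < p_trio
        links.append(
            PedigreeLink(
                case_id=c.case_id,
                proband_sample=c.case_id,
                mother_sample=f"{c.case_id}-M" if has_parents else None,
                father_sample=f"{c.case_id}-F" if has_parents else None,
            )
        )
    return links


# ---------------------------------------------------------------------------
# nuclear variants


def _draw_af(rng, n, pass_mask, cut, missing_prob, max_af=0.5):
    """Frequencies consistent with the pass/fail draw: passing variants get
    af < cut (or missing), failing ones af in [cut, max_af)."""
    af = np.where(
        pass_mask,
        rng.random(n) * cut,
        cut + rng.random(n) * (max_af - cut),
    )
    missing = pass_mask & (rng.random(n) < missing_prob)
    return af, missing


def _choice_from(rng, probs: dict) -> object:
    keys = list(probs)
    w = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=w / w.sum()))]


def generate_variants(
    cases: list[CaseRecord],
    config: GeneratorConfig,
    genes: list[GeneInfo] | None = None,
) -> list[VariantRecord]:
    """Per-sample annotated variant calls, cohort-pooled.

    Background calls land in genes with probability proportional to coding
    length and carry QC flags and frequencies drawn to reproduce the
    cascade's stage survivals; likely-pathogenic panel variants are planted
    per the configured histogram, with the causal subset marking the case
    molecular-autopsy positive (``ma_status`` is set on the cases).
    """
    config.validate()
    if genes is None:
        genes = build_gene_catalog(config)
    rng = config._rng("variants")
    lengths = np.array([g.length_kb for g in genes])
    gene_p = lengths / lengths.sum()
    panel_mask = np.array([g.in_panel for g in genes])
    noncausal_panel_idx = [i for i, g in enumerate(genes) if g.in_panel and not g.causal]
    causal_idx = [i for i, g in enumerate(genes) if g.causal]
    s1, s2, s3 = config.stage_survival
    hist = config.panel_likely_count_probs
    p_any = 1.0 - hist.get(0, 0.0)
    p_causal_given_any = config.ma_likely_rate / p_any if p_any > 0 else 0.0
    bg_effects = list(config.background_effect_probs)
    bg_effect_w = np.asarray([config.background_effect_probs[e] for e in bg_effects])
    bg_effect_w = bg_effect_w / bg_effect_w.sum()

    records: list[VariantRecord] = []
    for case in cases:
        sample = case.analysis_proband or case.case_id
        n_raw = int(rng.poisson(config.mean_raw_variants))
        gene_idx = rng.choice(len(genes), size=n_raw, p=gene_p)
        qc = rng.random(n_raw) < s1
        int_pass = rng.random(n_raw) < s2
        kg_pass = rng.random(n_raw) < s3
        af_int, int_missing = _draw_af(rng, n_raw, int_pass, 0.05, config.af_missing_prob)
        af_kg, kg_missing = _draw_af(rng, n_raw, kg_pass, 0.01, config.af_missing_prob)
        effect_ids = rng.choice(len(bg_effects), size=n_raw, p=bg_effect_w)
        offsets = rng.random(n_raw)
        ref_ids = rng.integers(0, 4, size=n_raw)
        alt_shift = rng.integers(1, 4, size=n_raw)
        cat_u = rng.random(n_raw)
        for j in range(n_raw):
            g = genes[gene_idx[j]]
            effect = bg_effects[effect_ids[j]]
            category = _category_from_u(config.category_probs[effect], cat_u[j])
            if panel_mask[gene_idx[j]] and category < 3:
                category = 3  # panel likely-pathogenic calls are planted only
            ref = _BASES[ref_ids[j]]
            alt = _BASES[(ref_ids[j] + alt_shift[j]) % 4]
            records.append(
                VariantRecord(
                    sample_id=sample,
                    chrom=g.chrom,
                    pos=g.start + int(offsets[j] * g.length_kb * 1000),
                    ref_allele=ref,
                    alt_allele=alt,
                    gene=g.symbol,
                    effect_class=effect,
                    qc_pass=bool(qc[j]),
                    af_internal=None if int_missing[j] else round(float(af_int[j]), 6),
                    af_1kg=None if kg_missing[j] else round(float(af_kg[j]), 6),
                    category=category,
                )
            )
        # planted likely-pathogenic panel variants
        k = int(_choice_from(rng, hist))
        causal = k >= 1 and rng.random() < p_causal_given_any
        for m in range(k):
            if causal and m == 0:
                g = genes[causal_idx[int(rng.integers(len(causal_idx)))]]
            else:
                g = genes[noncausal_panel_idx[int(rng.integers(len(noncausal_panel_idx)))]]
            effect = _choice_from(rng, config.likely_effect_probs)
            ref_i = int(rng.integers(4))
            records.append(
                VariantRecord(
                    sample_id=sample,
                    chrom=g.chrom,
                    pos=g.start + int(rng.random() * g.length_kb * 1000),
                    ref_allele=_BASES[ref_i],
                    alt_allele=_BASES[(ref_i + int(rng.integers(1, 4))) % 4],
                    gene=g.symbol,
                    effect_class=effect,
                    qc_pass=True,
                    af_internal=None,
                    af_1kg=None,
                    category=1 if effect == "missense" else 2,
                )
            )
        case.ma_status = "positive" if causal else "negative"
    return records


def _category_from_u(probs: dict[int, float], u: float) -> int:
    acc = 0.0
    total = sum(probs.values())
    for cat, p in probs.items():
        acc += p / total
        if u < acc:
            return cat
    return list(probs)[-1]


# ---------------------------------------------------------------------------
# mtDNA


def _mt_positions(rng, n, dloop_prob, used: set[int]) -> list[int]:
    out = []
    while len(out) < n:
        if rng.random() < dloop_prob:
            pos = int(rng.choice(_DLOOP_POSITIONS))
        else:
            pos = int(rng.choice(_NON_DLOOP_POSITIONS))
        if pos not in used:
            used.add(pos)
            out.append(pos)
    return out


def _mt_record(rng, config, sample, pos, hf) -> VariantRecord:
    depth = max(50, int(rng.poisson(config.mt_depth_mean)))
    alt_d = int(np.clip(round(hf * depth), 1, depth - 1))
    ref_i = int(rng.integers(4))
    af = None if rng.random() < 0.7 else round(float(rng.random() * 0.045), 6)
    return VariantRecord(
        sample_id=sample,
        chrom="MT",
        pos=pos,
        ref_allele=_BASES[ref_i],
        alt_allele=_BASES[(ref_i + int(rng.integers(1, 4))) % 4],
        gene=None,
        effect_class="other",
        qc_pass=True,
        af_1kg=af,
        zygosity="hemi",
        depth_ref=depth - alt_d,
        depth_alt=alt_d,
    )


def generate_mtdna(
    cases: list[CaseRecord],
    pedigree: list[PedigreeLink],
    config: GeneratorConfig,
) -> list[VariantRecord]:
    """Mitochondrial heteroplasmic calls for probands and parents.

    Infants draw their burden from a high-burden component (>= 10
    variants) with probability ``high_burden_infant_prob``; every proband
    variant is copied to the mother with probability
    ``maternal_transmission_prob`` with its heteroplasmic fraction jittered
    within the band; parents also get independent background variants.
    Positions are distinct within a family, so shared counts are exact.
    """
    config.validate()
    rng = config._rng("mtdna")
    by_case = {link.case_id: link for link in pedigree}
    lo, hi = config.hf_band
    records: list[VariantRecord] = []
    for case in cases:
        link = by_case.get(case.case_id)
        proband = link.proband_sample if link else case.case_id
        is_infant = case.age_months < 12.0
        if is_infant and rng.random() < config.high_burden_infant_prob:
            n = config.high_burden_min + int(rng.poisson(config.high_burden_extra_mean))
        else:
            r, mean = config.mt_baseline_r, config.mt_baseline_mean
            n = int(rng.negative_binomial(r, r / (r + mean)))
        used: set[int] = set()
        positions = _mt_positions(rng, n, config.dloop_prob, used)
        hfs = lo + rng.random(n) * (hi - lo)
        proband_records = [_mt_record(rng, config, proband, p, h) for p, h in zip(positions, hfs)]
        records.extend(proband_records)
        if link is None or link.mother_sample is None:
            continue
        for rec, hf in zip(proband_records, hfs):
            if rng.random() < config.maternal_transmission_prob:
                hf_m = float(np.clip(hf + rng.uniform(-config.hf_noise, config.hf_noise), lo, hi))
                depth = max(50, int(rng.poisson(config.mt_depth_mean)))
                alt_d = int(np.clip(round(hf_m * depth), 1, depth - 1))
                records.append(
                    VariantRecord(
                        sample_id=link.mother_sample,
                        chrom="MT",
                        pos=rec.pos,
                        ref_allele=rec.ref_allele,
                        alt_allele=rec.alt_allele,
                        effect_class="other",
                        qc_pass=True,
                        af_1kg=rec.af_1kg,
                        zygosity="hemi",
                        depth_ref=depth - alt_d,
                        depth_alt=alt_d,
                    )
                )
        for parent, mean_bg in (
            (link.mother_sample, config.mother_background_mean),
            (link.father_sample, config.father_background_mean),
        ):
            if parent is None:
                continue
            n_bg = int(rng.poisson(mean_bg))
            for pos in _mt_positions(rng, n_bg, config.dloop_prob, used):
                hf = lo + rng.random() * (hi - lo)
                records.append(_mt_record(rng, config, parent, pos, hf))
    return records


# ---------------------------------------------------------------------------
# full-cohort convenience


def generate_cohort(config: GeneratorConfig, outdir: str | Path | None = None) -> dict:
    """Generate cases, pedigree, nuclear and mtDNA variants (and optionally
    write them under ``outdir`` as TSV/plain-text)."""
    genes = build_gene_catalog(config)
    cases = generate_cases(config)
    pedigree = generate_pedigree(cases, config)
    variants = generate_variants(cases, config, genes=genes)
    mt = generate_mtdna(cases, pedigree, config)
    out = {
        "cases": cases,
        "pedigree": pedigree,
        "variants": variants,
        "mtdna": mt,
        "genes": genes,
        "panel": panel_of(genes),
        "causal_panel": causal_panel_of(genes),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_case_table(cases, outdir / "cases.tsv")
        write_pedigree(pedigree, outdir / "pedigree.tsv")
        write_variant_table(variants, outdir / "variants.tsv")
        write_variant_table(mt, outdir / "mtdna.tsv")
        write_panel(out["panel"], outdir / "panel.txt")
        write_panel(out["causal_panel"], outdir / "causal_genes.txt")
    return out
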