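"""Domain types and readers/writers for molecular-autopsy cohort data.

The pipeline consumes four kinds of inputs:

* per-sample annotated variant tables (VCF 4.x with a documented INFO
  dialect, or a flat TSV with one column per field),
* a case-metadata table (demographics, forensic/molecular autopsy status,
  death timestamp),
* a gene-panel list (plain text, one symbol per line),
* a pedigree table linking proband, mother and father sample ids.

Two tables transcribed from the source study are packaged as golden
fixtures: the 50-case cohort summary (``table1_cases``) and the eight
high-burden mtDNA heteroplasmy cases (``table3_mtdna``).

All coordinates are 1-based inclusive, matching VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

MT_CONTIGS = {"MT", "CHRM", "M", "CHRMT"}

EFFECT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice",
    "synonymous",
    "noncoding",
    "other",
)

ZYGOSITIES = ("het", "hom", "hemi")

#: INFO/FORMAT keys of the annotated-VCF dialect.  The annotations of the
#: original study came from a proprietary engine, so the key names are a
#: documented convention of this package; pass a ``key_map`` to the VCF
#: reader to rebind them.
VCF_KEYS = {
    "gene": "GENE",
    "effect": "EFFECT",
    "af_internal": "AF_INT",
    "af_1kg": "AF_1KG",
    "category": "CAT",
    "hgvs_c": "HGVS_C",
}

VARIANT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "gene",
    "effect_class",
    "qc_pass",
    "af_internal",
    "af_1kg",
    "category",
    "zygosity",
    "depth_ref",
    "depth_alt",
    "hgvs_c",
]


class FormatError(ValueError):
    """A table or file cannot be parsed as the expected format."""


def normalize_gene(symbol: str) -> str:
    return symbol.strip().upper()


def is_mitochondrial(chrom: str) -> bool:
    return chrom.upper().removeprefix("CHR") in {"M", "MT"}


@dataclass(slots=True)
class VariantRecord:
    """One annotated variant call in one sample.

    ``af_internal`` is the allele frequency in the study's internal database,
    ``af_1kg`` the 1000 Genomes frequency; both may be missing (``None``) for
    novel variants.  ``category`` is the ordinal pathogenicity tier
    (1 = reported recognized cause ... 5 = lowest), missing when the input
    carries no annotation.  ``depth_ref``/``depth_alt`` are allelic read
    depths, required for mitochondrial heteroplasmy analysis.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str | None = None
    effect_class: str = "other"
    qc_pass: bool = True
    af_internal: float | None = None
    af_1kg: float | None = None
    category: int | None = None
    zygosity: str = "het"
    depth_ref: int | None = None
    depth_alt: int | None = None
    hgvs_c: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise FormatError("ref and alt alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}")
        for name in ("af_internal", "af_1kg"):
            af = getattr(self, name)
            if af is not None and not 0.0 <= af <= 1.0:
                raise FormatError(f"{name}={af} outside [0,1] at {self.chrom}:{self.pos}")
        if self.category is not None and self.category not in (1, 2, 3, 4, 5):
            raise FormatError(f"category must be 1-5, got {self.category}")
        if self.effect_class not in EFFECT_CLASSES:
            raise FormatError(f"unknown effect class {self.effect_class!r}")
        if self.zygosity not in ZYGOSITIES:
            raise FormatError(f"unknown zygosity {self.zygosity!r}")
        for name in ("depth_ref", "depth_alt"):
            d = getattr(self, name)
            if d is not None and d < 0:
                raise FormatError(f"{name} must be non-negative, got {d}")

    @property
    def is_mitochondrial(self) -> bool:
        return is_mitochondrial(self.chrom)

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class CaseRecord:
    """One molecular-autopsy case.

    Ages are stored in the unit of the source table (``months`` for infants,
    ``years`` otherwise) and normalized via :attr:`age_months`.  The single
    sibling-pair case contributes two probands but exactly one analysis
    proband (the forensic-autopsy-negative sibling); ``sibling_ages_months``
    then records both ages and :attr:`youngest_age_months` is used for the
    age-group assignment of the case.
    """

    case_id: str
    age_value: float
    age_unit: str  # "months" | "years"
    sex: str  # "female" | "male"
    fa_status: str  # forensic autopsy: "positive" | "negative"
    ma_status: str | None = None  # molecular autopsy; None = to be computed
    race: str | None = None
    fa_summary: str = ""
    proband_ids: list[str] = field(default_factory=list)
    analysis_proband: str | None = None
    sibling_ages_months: tuple[float, ...] | None = None
    sibling_fa_statuses: tuple[str, ...] | None = None
    sibling_ma_statuses: tuple[str, ...] | None = None
    death_time: datetime | None = None
    site_label: str = ""
    include_in_cohort: bool = True

    def __post_init__(self) -> None:
        if self.age_unit not in ("months", "years"):
            raise FormatError(f"bad age unit {self.age_unit!r} for case {self.case_id}")
        if self.age_value < 0:
            raise FormatError(f"negative age for case {self.case_id}")
        if self.sex not in ("female", "male"):
            raise FormatError(f"bad sex {self.sex!r} for case {self.case_id}")
        for name in ("fa_status", "ma_status"):
            v = getattr(self, name)
            if v is not None and v not in ("positive", "negative"):
                raise FormatError(f"bad {name} {v!r} for case {self.case_id}")
        if not self.proband_ids:
            self.proband_ids = [self.case_id]
        if self.analysis_proband is None:
            self.analysis_proband = self.proband_ids[0]
        if not self.site_label:
            self.site_label = self.case_id[:4]

    @property
    def age_months(self) -> float:
        """Age of the analysis proband, in months."""
        return self.age_value if self.age_unit == "months" else self.age_value * 12.0

    @property
    def youngest_age_months(self) -> float:
        if self.sibling_ages_months:
            return min(self.sibling_ages_months)
        return self.age_months


@dataclass(frozen=True)
class PanelDefinition:
    """A named set of gene symbols defining a restriction scope."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"panel {self.name!r} is empty")
        normalized = frozenset(normalize_gene(g) for g in self.genes)
        object.__setattr__(self, "genes", normalized)

    def __contains__(self, gene: str | None) -> bool:
        return gene is not None and normalize_gene(gene) in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(slots=True)
class PedigreeLink:
    """Proband/mother/father sample ids for one case."""

    case_id: str
    proband_sample: str
    mother_sample: str | None = None
    father_sample: str | None = None
    other_relatives: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.proband_sample:
            raise FormatError(f"pedigree row for {self.case_id} lacks a proband sample")
        samples = [self.proband_sample, self.mother_sample, self.father_sample, *self.other_relatives]
        samples = [s for s in samples if s]
        if len(samples) != len(set(samples)):
            raise FormatError(f"pedigree row for {self.case_id} repeats a sample id")


# ---------------------------------------------------------------------------
# variant tables


def _opt_float(value) -> float | None:
    if value is None or value == "" or pd.isna(value):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    if value is None or value == "" or pd.isna(value):
        return None
    return int(float(value))


def _opt_str(value) -> str | None:
    if value is None or pd.isna(value) or value == "":
        return None
    return str(value)


_BOOL_STRINGS = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    try:
        return _BOOL_STRINGS[str(value).strip().lower()]
    except KeyError:
        raise FormatError(f"cannot parse boolean {value!r}") from None


def read_variant_table(path: str | Path, dialect: str = "tsv", key_map: dict | None = None) -> list[VariantRecord]:
    """Read an annotated variant table.

    ``dialect="tsv"`` expects one column per :class:`VariantRecord` field;
    ``dialect="vcf"`` expects annotation keys GENE, EFFECT, AF_INT, AF_1KG,
    CAT in INFO and AD in the genotype column (rebind via ``key_map``).
    Multi-allelic VCF rows are split into one record per alternate allele.
    Rows failing type checks are logged with their line number and excluded;
    an unreadable file or a missing mandatory column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path, key_map=key_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variant_tsv(path: Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = ["sample_id", "chrom", "pos", "ref_allele", "alt_allele"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = row._asdict()
        try:
            records.append(
                VariantRecord(
                    sample_id=d["sample_id"],
                    chrom=d["chrom"],
                    pos=int(d["pos"]),
                    ref_allele=d["ref_allele"],
                    alt_allele=d["alt_allele"],
                    gene=_opt_str(d.get("gene", "")),
                    effect_class=d.get("effect_class") or "other",
                    qc_pass=_parse_bool(d.get("qc_pass", True)),
                    af_internal=_opt_float(d.get("af_internal", "")),
                    af_1kg=_opt_float(d.get("af_1kg", "")),
                    category=_opt_int(d.get("category", "")),
                    zygosity=d.get("zygosity") or "het",
                    depth_ref=_opt_int(d.get("depth_ref", "")),
                    depth_alt=_opt_int(d.get("depth_alt", "")),
                    hgvs_c=_opt_str(d.get("hgvs_c", "")),
                )
            )
        except (FormatError, ValueError) as exc:
            logger.warning("%s line %d: skipping malformed row (%s)", path, i, exc)
    return records


def _read_variant_vcf(path: Path, key_map: dict | None = None) -> list[VariantRecord]:
    import pysam

    keys = dict(VCF_KEYS)
    if key_map:
        keys.update(key_map)
    def info_get(info, key):
        # pysam raises on keys absent from the header; treat as missing
        try:
            return info.get(key)
        except (KeyError, ValueError):
            return None

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            info = rec.info
            qc_pass = len(rec.filter) == 0 or "PASS" in rec.filter
            for alt_index, alt in enumerate(rec.alts or ()):
                common = dict(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    gene=_scalar(info_get(info, keys["gene"])),
                    effect_class=_scalar(info_get(info, keys["effect"])) or "other",
                    qc_pass=qc_pass,
                    af_internal=_per_alt(info_get(info, keys["af_internal"]), alt_index),
                    af_1kg=_per_alt(info_get(info, keys["af_1kg"]), alt_index),
                    category=_opt_int(_per_alt(info_get(info, keys["category"]), alt_index)),
                    hgvs_c=_scalar(info_get(info, keys["hgvs_c"])),
                )
                for name in sample_names:
                    call = rec.samples[name]
                    gt = call.get("GT")
                    if gt is None or all(a in (None, 0) for a in gt):
                        continue
                    if (alt_index + 1) not in gt:
                        continue
                    called = [a for a in gt if a is not None]
                    if len(called) == 1:
                        zygosity = "hemi"
                    elif all(a == alt_index + 1 for a in called):
                        zygosity = "hom"
                    else:
                        zygosity = "het"
                    ad = call.get("AD")
                    depth_ref = depth_alt = None
                    if ad is not None and ad[0] is not None:
                        depth_ref = int(ad[0])
                        if len(ad) > alt_index + 1 and ad[alt_index + 1] is not None:
                            depth_alt = int(ad[alt_index + 1])
                    try:
                        records.append(
                            VariantRecord(
                                sample_id=name, zygosity=zygosity,
                                depth_ref=depth_ref, depth_alt=depth_alt, **common,
                            )
                        )
                    except FormatError as exc:
                        logger.warning("%s %s:%d: skipping malformed record (%s)", path, rec.chrom, rec.pos, exc)
    return records


def _scalar(value):
    if isinstance(value, tuple):
        value = value[0] if value else None
    return None if value is None else str(value)


def _per_alt(value, alt_index: int):
    if value is None:
        return None
    if isinstance(value, tuple):
        if alt_index < len(value):
            value = value[alt_index]
        else:
            value = value[0]
    if value is None:
        return None
    # htslib floats are single precision; round away the representation noise
    return round(float(value), 6)


def write_variant_table(records: list[VariantRecord], path: str | Path) -> None:
    """Write records as TSV; a re-read reproduces them field-by-field."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref_allele": r.ref_allele,
                "alt_allele": r.alt_allele,
                "gene": r.gene if r.gene is not None else "",
                "effect_class": r.effect_class,
                "qc_pass": r.qc_pass,
                "af_internal": "" if r.af_internal is None else repr(r.af_internal),
                "af_1kg": "" if r.af_1kg is None else repr(r.af_1kg),
                "category": "" if r.category is None else r.category,
                "zygosity": r.zygosity,
                "depth_ref": "" if r.depth_ref is None else r.depth_ref,
                "depth_alt": "" if r.depth_alt is None else r.depth_alt,
                "hgvs_c": r.hgvs_c if r.hgvs_c is not None else "",
            }
        )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def variants_to_frame(records: list[VariantRecord]) -> pd.DataFrame:
    """Tabular view of a record list (column per field)."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in VARIANT_COLUMNS} for r in records],
        columns=VARIANT_COLUMNS,
    )


# ---------------------------------------------------------------------------
# case tables


def _parse_age(text: str) -> tuple[float, str]:
    """Parse the mixed age dialect: '3 months' -> months, '44' -> years."""
    text = text.strip()
    if text.lower().endswith("months") or text.lower().endswith("month"):
        return float(text.split()[0]), "months"
    return float(text), "years"


def read_case_table(path: str | Path) -> list[CaseRecord]:
    """Read a case-metadata TSV into :class:`CaseRecord` objects.

    Ages may be written as "3 months" or as numeric years.  A sibling-pair
    row writes both ages as "17/24" and both statuses slash-separated; it
    expands to one record whose analysis proband is the forensic-autopsy-
    negative sibling, with both ages kept in ``sibling_ages_months``.
    Duplicate case ids and unparseable ages are fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "case_id" not in df.columns or "age" not in df.columns:
        raise FormatError(f"{path}: case table needs at least case_id and age columns")
    cases: list[CaseRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        case_id = row["case_id"].strip()
        if case_id in seen:
            raise FormatError(f"{path}: duplicate case_id {case_id}")
        seen.add(case_id)
        try:
            cases.append(_parse_case_row(row, case_id))
        except (FormatError, ValueError, IndexError) as exc:
            raise FormatError(f"{path} row {i + 2} ({case_id}): {exc}") from exc
    return cases


def _parse_case_row(row, case_id: str) -> CaseRecord:
    age_text = row["age"].strip()
    sex = row.get("sex", "").strip().lower().rstrip("s")  # "Males" -> "male"
    race = _opt_str(row.get("race", "")) if row.get("race", "") else None
    fa = row.get("fa_status", "").strip().lower()
    ma_raw = row.get("ma_status", "").strip().lower()
    fa_summary = row.get("fa_summary", "").strip()
    death_time = None
    if row.get("death_time", ""):
        death_time = datetime.fromisoformat(row["death_time"].strip())
    site = row.get("site_label", "").strip()

    if "/" in age_text:  # sibling-pair row
        ages = [_parse_age(a) for a in age_text.split("/")]
        fa_parts = [p.strip().lower() for p in fa.split("/")]
        ma_parts = [p.strip().lower() for p in ma_raw.split("/")] if ma_raw else [None] * len(ages)
        summaries = fa_summary.split("/") if "/" in fa_summary else [fa_summary] * len(ages)
        if len(fa_parts) != len(ages):
            raise FormatError("sibling ages and forensic statuses disagree in count")
        # analysis proband: the forensic-autopsy-negative sibling
        try:
            idx = fa_parts.index("negative")
        except ValueError:
            idx = 0
        ages_months = tuple(a * 12.0 if u == "years" else a for a, u in ages)
        proband_ids = [f"{case_id}.{k + 1:02d}P" for k in range(len(ages))]
        return CaseRecord(
            case_id=case_id,
            age_value=ages[idx][0],
            age_unit=ages[idx][1],
            sex=sex,
            race=race,
            fa_status=fa_parts[idx],
            ma_status=ma_parts[idx],
            fa_summary=summaries[idx].strip() if idx < len(summaries) else fa_summary,
            proband_ids=proband_ids,
            analysis_proband=proband_ids[idx],
            sibling_ages_months=ages_months,
            sibling_fa_statuses=tuple(fa_parts),
            sibling_ma_statuses=tuple(p for p in ma_parts if p) or None,
            death_time=death_time,
            site_label=site,
        )

    age_value, age_unit = _parse_age(age_text)
    return CaseRecord(
        case_id=case_id,
        age_value=age_value,
        age_unit=age_unit,
        sex=sex,
        race=race,
        fa_status=fa,
        ma_status=ma_raw or None,
        fa_summary=fa_summary,
        death_time=death_time,
        site_label=site,
    )


def write_case_table(cases: list[CaseRecord], path: str | Path) -> None:
    rows = []
    for c in cases:
        if c.sibling_ages_months:
            age = "/".join(
                f"{m / 12:g}" if m >= 12 else f"{m:g} months" for m in c.sibling_ages_months
            )
        elif c.age_unit == "months":
            age = f"{c.age_value:g} months"
        else:
            age = f"{c.age_value:g}"
        fa = "/".join(c.sibling_fa_statuses) if c.sibling_fa_statuses else c.fa_status
        ma = "/".join(c.sibling_ma_statuses) if c.sibling_ma_statuses else (c.ma_status or "")
        rows.append(
            {
                "case_id": c.case_id,
                "age": age,
                "sex": c.sex,
                "race": c.race or "",
                "fa_status": fa,
                "fa_summary": c.fa_summary,
                "ma_status": ma,
                "death_time": c.death_time.isoformat() if c.death_time else "",
                "site_label": c.site_label,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# panels and pedigrees


def read_panel(path: str | Path, name: str | None = None) -> PanelDefinition:
    """Read a plain-text gene list (one symbol per line, '#' comments)."""
    path = Path(path)
    genes = set()
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(normalize_gene(line))
    if not genes:
        raise FormatError(f"panel file {path} contains no gene symbols")
    return PanelDefinition(name=name or path.stem, genes=frozenset(genes))


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(panel.genes)) + "\n")


def read_pedigree(path: str | Path) -> list[PedigreeLink]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    links = []
    for _, row in df.iterrows():
        links.append(
            PedigreeLink(
                case_id=row["case_id"],
                proband_sample=row["proband_sample"],
                mother_sample=row.get("mother_sample", "") or None,
                father_sample=row.get("father_sample", "") or None,
                other_relatives=[s for s in row.get("other_relatives", "").split(",") if s],
            )
        )
    return links


def write_pedigree(links: list[PedigreeLink], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "case_id": l.case_id,
                "proband_sample": l.proband_sample,
                "mother_sample": l.mother_sample or "",
                "father_sample": l.father_sample or "",
                "other_relatives": ",".join(l.other_relatives),
            }
            for l in links
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged fixtures

_FIXTURES = {
    "table1_cases": "table1_cases.tsv",
    "table3_mtdna": "table3_mtdna.tsv",
    "rcrs_loci": "rcrs_loci.tsv",
    "known_pathogenic": "known_pathogenic.tsv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture table."""
    try:
        filename = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}") from None
    return Path(str(resources.files("molautopsy.data") / filename))


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table as a DataFrame.

    ``table1_cases`` is the 50-case cohort summary; ``table3_mtdna`` the
    per-case mtDNA heteroplasmic-variant counts (all/D-loop, with parental
    shared counts where the trio was sequenced).  Empty cells mean the value
    was not printed (e.g. parents not sequenced).
    """
    df = pd.read_csv(fixture_path(name), sep="\t", dtype=str, keep_default_na=False)
    if name == "table3_mtdna":
        for col in df.columns:
            if col != "case_id":
                df[col] = pd.to_numeric(df[col].replace("", pd.NA))
    if name == "rcrs_loci":
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    return df


def load_cohort_cases() -> list[CaseRecord]:
    """The packaged 50-case cohort as :class:`CaseRecord` objects."""
    return read_case_table(fixture_path("table1_cases"))


def load_known_pathogenic() -> set[tuple[str, str]]:
    """Packaged (gene, cDNA-change) lookup of reported causal variants."""
    df = load_fixture("known_pathogenic")
    return {(normalize_gene(g), c) for g, c in zip(df["gene"], df["hgvs_c"])}
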