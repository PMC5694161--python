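"""Synthetic-cohort generator: determinism, planted-parameter recovery,
and compatibility of its outputs with the readers."""

import logging

import numpy as np
import pytest

from molautopsy import cascade, io, mtdna, panel
from molautopsy.simulate import (
    GeneratorConfig,
    build_gene_catalog,
    causal_panel_of,
    generate_cases,
    generate_cohort,
    generate_mtdna,
    generate_pedigree,
    generate_variants,
    panel_of,
)


def profiles_by_sample(records):
    by_s = {}
    for v in records:
        by_s.setdefault(v.sample_id, []).append(v)
    return {s: mtdna.filter_heteroplasmic(r) for s, r in by_s.items()}


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = GeneratorConfig(n_cases=30, seed=11, mean_raw_variants=200)
        a = generate_cohort(cfg)
        b = generate_cohort(GeneratorConfig(n_cases=30, seed=11, mean_raw_variants=200))
        assert [c.case_id for c in a["cases"]] == [c.case_id for c in b["cases"]]
        assert [c.age_months for c in a["cases"]] == [c.age_months for c in b["cases"]]
        assert a["variants"] == b["variants"]
        assert a["mtdna"] == b["mtdna"]

    def test_different_seed_differs(self):
        a = generate_cases(GeneratorConfig(n_cases=30, seed=1))
        b = generate_cases(GeneratorConfig(n_cases=30, seed=2))
        assert [c.age_months for c in a] != [c.age_months for c in b]

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="sex_male_prob"):
            GeneratorConfig(sex_male_prob=1.4).validate()
        with pytest.raises(ValueError, match="ma_likely_rate"):
            GeneratorConfig(ma_likely_rate=0.9).validate()


class TestCaseGeneration:
    CFG = GeneratorConfig(n_cases=5000, seed=21)

    @pytest.fixture(scope="class")
    def cases(self):
        return generate_cases(self.CFG)

    def test_sex_ratio_recovered(self, cases):
        male = sum(1 for c in cases if c.sex == "male") / len(cases)
        se = np.sqrt(0.62 * 0.38 / len(cases))
        assert male == pytest.approx(0.62, abs=3 * se)

    def test_infant_fraction_recovered(self, cases):
        infants = sum(1 for c in cases if c.age_months < 12) / len(cases)
        se = np.sqrt(0.16 * 0.84 / len(cases))
        assert infants == pytest.approx(0.16, abs=3 * se)

    def test_forensic_positivity_increases_with_age(self, cases):
        infants = [c for c in cases if c.age_months < 12]
        adults = [c for c in cases if c.age_months > 360]
        fa_rate = lambda group: sum(1 for c in group if c.fa_status == "positive") / len(group)
        assert fa_rate(infants) < 0.1 < fa_rate(adults)

    def test_infant_deaths_cluster_midweek(self, cases):
        infants = [c for c in cases if c.age_months < 12]
        midweek = sum(1 for c in infants if c.death_time.weekday() in (2, 3)) / len(infants)
        assert midweek == pytest.approx(0.87, abs=0.05)


class TestVariantGeneration:
    CFG = GeneratorConfig(n_cases=120, seed=5, mean_raw_variants=3000)

    @pytest.fixture(scope="class")
    def cohort(self):
        genes = build_gene_catalog(self.CFG)
        cases = generate_cases(self.CFG)
        variants = generate_variants(cases, self.CFG, genes=genes)
        return cases, genes, variants

    def test_gene_counts_scale_with_length(self, cohort):
        _, genes, variants = cohort
        counts = {}
        for v in variants:
            counts[v.gene] = counts.get(v.gene, 0) + 1
        by_symbol = {g.symbol: g for g in genes}
        big = max(genes, key=lambda g: g.length_kb)
        small = min(genes, key=lambda g: g.length_kb)
        ratio_counts = counts.get(big.symbol, 0) / max(counts.get(small.symbol, 1), 1)
        ratio_lengths = big.length_kb / small.length_kb
        assert ratio_counts == pytest.approx(ratio_lengths, rel=0.5)

    def test_stage_survival_recovered_within_3_se(self, cohort):
        cases, _, variants = cohort
        _, reports = cascade.apply_cascade_cohort(variants)
        n_raw = sum(r.n_raw for r in reports.values())
        s1, s2, s3 = self.CFG.stage_survival
        n_qc = sum(r.n_qc for r in reports.values())
        planted = sum(1 for v in variants if v.category in (1, 2) and v.af_internal is None and v.af_1kg is None and v.qc_pass)
        # QC stage: background survives with prob s1, planted always pass
        expect = s1
        obs = (n_qc - planted) / (n_raw - planted)
        se = np.sqrt(expect * (1 - expect) / n_raw)
        assert obs == pytest.approx(expect, abs=3 * se)

    def test_retention_matches_configured_cascade_shape(self, cohort):
        cases, _, variants = cohort
        _, reports = cascade.apply_cascade_cohort(variants)
        n_raw = sum(r.n_raw for r in reports.values())
        n_final = sum(r.n_final for r in reports.values())
        expected_planted = self.CFG.expected_panel_likely_mean * len(cases)
        expect = (self.CFG.expected_background_retention * (n_raw - expected_planted) + expected_planted) / n_raw
        se = np.sqrt(expect * (1 - expect) / n_raw)
        assert n_final / n_raw == pytest.approx(expect, abs=4 * se)

    def test_positive_rate_matches_planted_status(self, cohort):
        cases, genes, variants = cohort
        survivors, _ = cascade.apply_cascade_cohort(variants)
        causal = causal_panel_of(genes)
        by_s = {}
        for v in survivors:
            by_s.setdefault(v.sample_id, []).append(v)
        for c in cases:
            got = cascade.classify_report(by_s.get(c.case_id, []), causal)
            assert got == c.ma_status

    def test_panel_share_of_final_variants(self, cohort):
        cases, genes, variants = cohort
        survivors, _ = cascade.apply_cascade_cohort(variants)
        pnl = panel_of(genes)
        share = len(panel.restrict_to_panel(survivors, pnl)) / len(survivors)
        n_bg = self.CFG.expected_background_retention * self.CFG.mean_raw_variants
        n_planted = self.CFG.expected_panel_likely_mean
        expect = (self.CFG.panel_length_share * n_bg + n_planted) / (n_bg + n_planted)
        assert share == pytest.approx(expect, rel=0.3)


class TestMtdnaGeneration:
    def test_full_transmission_means_shared_equals_total(self):
        cfg = GeneratorConfig(n_cases=150, seed=9, infant_weight=0.3)
        cases = generate_cases(cfg)
        ped = generate_pedigree(cases, cfg)
        profs = profiles_by_sample(generate_mtdna(cases, ped, cfg))
        checked = 0
        for link in ped:
            if link.mother_sample is None or link.proband_sample not in profs:
                continue
            p = mtdna.maternal_sharing(
                profs[link.proband_sample],
                profs.get(link.mother_sample, mtdna.HeteroplasmyProfile(link.mother_sample)),
            )
            assert p.shared_with_mother == p.n_total
            checked += 1
        assert checked > 20

    def test_zero_transmission_shares_nothing(self):
        # family positions are drawn without replacement, so with no
        # transmission the intersection is empty by construction
        cfg = GeneratorConfig(n_cases=60, seed=9, infant_weight=0.3, maternal_transmission_prob=0.0)
        cases = generate_cases(cfg)
        ped = generate_pedigree(cases, cfg)
        profs = profiles_by_sample(generate_mtdna(cases, ped, cfg))
        for link in ped:
            if link.mother_sample is None or link.proband_sample not in profs:
                continue
            p = mtdna.maternal_sharing(
                profs[link.proband_sample],
                profs.get(link.mother_sample, mtdna.HeteroplasmyProfile(link.mother_sample)),
            )
            assert p.shared_with_mother == 0

    def test_high_burden_infant_fraction(self):
        from scipy.stats import nbinom

        cfg = GeneratorConfig(n_cases=1000, seed=13, infant_weight=1.0)
        cases = generate_cases(cfg)
        ped = generate_pedigree(cases, cfg)
        profs = profiles_by_sample(generate_mtdna(cases, ped, cfg))
        hb = sum(1 for l in ped if l.proband_sample in profs and profs[l.proband_sample].high_burden)
        frac = hb / len(cases)
        r, mean = cfg.mt_baseline_r, cfg.mt_baseline_mean
        p_tail = float(nbinom.sf(cfg.high_burden_min - 1, r, r / (r + mean)))
        expect = cfg.high_burden_infant_prob + (1 - cfg.high_burden_infant_prob) * p_tail
        se = np.sqrt(expect * (1 - expect) / len(cases))
        assert frac == pytest.approx(expect, abs=3 * se)


class TestWrittenTablesAreReadable:
    def test_round_trip_through_files_without_warnings(self, tmp_path, caplog):
        cfg = GeneratorConfig(n_cases=15, seed=3, mean_raw_variants=100)
        with caplog.at_level(logging.WARNING):
            out = generate_cohort(cfg, outdir=tmp_path)
            cases = io.read_case_table(tmp_path / "cases.tsv")
            variants = io.read_variant_table(tmp_path / "variants.tsv")
            mt = io.read_variant_table(tmp_path / "mtdna.tsv")
            ped = io.read_pedigree(tmp_path / "pedigree.tsv")
            pnl = io.read_panel(tmp_path / "panel.txt")
        assert not caplog.records
        assert len(cases) == 15
        assert variants == out["variants"]
        assert mt == out["mtdna"]
        assert ped == out["pedigree"]
        assert pnl.genes == out["panel"].genes
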