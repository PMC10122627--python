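"""Synthetic cohort generator: determinism, Hardy-Weinberg moments, truth."""

import numpy as np
import pytest

from varburden import (
    SimulationConfig,
    select_qualifying,
    simulate_case_cohort,
    simulate_control_summary,
    simulate_gene_panel,
    simulate_site_afs,
)
from varburden.calibration import run_calibration_experiment
from varburden.simulate import SimSite, site_gamma, write_simulated_vcf


def _small_cfg(**kw):
    base = dict(n_cases=40, n_controls=3000, n_genes=4,
                rare_sites_per_gene=10, common_sites_per_gene=3, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


class TestPanel:
    def test_requested_gene_count_with_disjoint_ranges(self):
        cfg = SimulationConfig(n_genes=8, seed=3)
        panel = simulate_gene_panel(cfg)
        assert len(panel) == 8
        spans = {}
        for m in panel:
            spans.setdefault(m.chrom, []).append(m.span)
        for chrom_spans in spans.values():
            chrom_spans.sort()
            for (s1, e1), (s2, e2) in zip(chrom_spans, chrom_spans[1:]):
                assert e1 <= s2

    def test_same_seed_identical_panels(self):
        cfg = SimulationConfig(seed=5)
        p1 = simulate_gene_panel(cfg)
        p2 = simulate_gene_panel(cfg)
        assert [(m.gene, m.chrom, m.exons) for m in p1] == [
            (m.gene, m.chrom, m.exons) for m in p2
        ]

    def test_x_gene_generated_then_excluded_by_selection_mode(self):
        cfg = _small_cfg(include_x_gene=True)
        panel = simulate_gene_panel(cfg)
        assert panel[-1].chrom == "X"
        # downstream exclusion is the caller's job (autosome-only loading);
        # the generator merely provides the exercise case
        autosomal = [m for m in panel if m.chrom != "X"]
        assert len(autosomal) == cfg.n_genes


class TestSiteAfs:
    def test_rare_and_common_frequency_ranges_respected(self):
        cfg = _small_cfg(indel_rate=0, multiallelic_rate=0, outside_rate=0)
        sites = simulate_site_afs(simulate_gene_panel(cfg), cfg)
        for s in sites:
            lo, hi = (cfg.common_freq if s.is_common else cfg.rare_freq)
            assert lo <= s.freq <= hi

    def test_zero_common_sites_config_respected(self):
        cfg = _small_cfg(common_sites_per_gene=0)
        sites = simulate_site_afs(simulate_gene_panel(cfg), cfg)
        assert all(s.freq <= cfg.rare_freq[1] for s in sites)

    def test_missense_fraction_labelling(self):
        cfg = _small_cfg(rare_sites_per_gene=100, n_genes=8,
                         missense_fraction=0.5, indel_rate=0,
                         multiallelic_rate=0)
        sites = simulate_site_afs(simulate_gene_panel(cfg), cfg)
        frac = np.mean(["missense_variant" in s.consequences for s in sites])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(sites))

    def test_outside_site_is_non_qualifying(self):
        cfg = _small_cfg(outside_rate=0.5, indel_rate=0)
        panel = simulate_gene_panel(cfg)
        sites = simulate_site_afs(panel, cfg)
        outside = [s for s in sites if not s.in_exon]
        assert outside, "config should generate off-exon spike-ins"
        models = {m.gene: m for m in panel}
        for s in outside:
            assert not models[s.gene].contains(s.chrom, s.pos)

    def test_site_keys_unique(self):
        cfg = _small_cfg(multiallelic_rate=0.3, outside_rate=0.2)
        sites = simulate_site_afs(simulate_gene_panel(cfg), cfg)
        keys = [s.key for s in sites]
        assert len(keys) == len(set(keys))


class TestControlSummary:
    def test_constructional_invariants(self):
        cfg = _small_cfg()
        sites = simulate_site_afs(simulate_gene_panel(cfg), cfg)
        for s in simulate_control_summary(sites, cfg):
            assert 0 <= s.ac <= s.an
            assert 2 * s.nhomalt <= s.ac
            assert s.an <= 2 * cfg.n_controls

    def test_zero_frequency_gives_zero_counts(self):
        cfg = _small_cfg(an_missing_rate=0)
        site = SimSite(gene="G", chrom="1", pos=10, ref="A", alt="G",
                       freq=0.0, consequences={"missense_variant"})
        (out,) = simulate_control_summary([site], cfg)
        assert out.ac == 0 and out.nhomalt == 0

    def test_half_frequency_moment(self):
        cfg = SimulationConfig(n_controls=20_000, an_missing_rate=0, seed=4)
        site = SimSite(gene="G", chrom="1", pos=10, ref="A", alt="G",
                       freq=0.5, consequences=set())
        (out,) = simulate_control_summary([site], cfg)
        n = 2 * cfg.n_controls
        sd = np.sqrt(n * 0.25)
        assert abs(out.ac - 0.5 * n) < 3 * sd


class TestCaseCohort:
    def test_same_seed_byte_identical_vcf(self, tmp_path):
        cfg = _small_cfg(multiallelic_rate=0.2)
        paths = []
        for name in ("a.vcf", "b.vcf"):
            rng = np.random.default_rng(cfg.seed)
            panel = simulate_gene_panel(cfg, rng)
            sites = simulate_site_afs(panel, cfg, rng)
            cohort = simulate_case_cohort(sites, cfg, rng)
            p = tmp_path / name
            write_simulated_vcf(cohort, p)
            paths.append(p.read_text())
        assert paths[0] == paths[1]

    def test_null_gamma_matches_control_frequency(self):
        cfg = _small_cfg(n_cases=5000, n_genes=1, rare_sites_per_gene=0,
                         common_sites_per_gene=5, genotype_missing_rate=0)
        rng = np.random.default_rng(cfg.seed)
        panel = simulate_gene_panel(cfg, rng)
        sites = simulate_site_afs(panel, cfg, rng)
        cohort = simulate_case_cohort(sites, cfg, rng)
        by_key = cohort.by_key()
        for s in sites:
            dos = by_key[s.key].dosages
            est = dos[dos >= 0].mean() / 2
            sd = np.sqrt(s.freq * (1 - s.freq) / (2 * cfg.n_cases))
            assert abs(est - s.freq) < 4 * sd

    def test_enrichment_raises_carrier_rate(self):
        # Hardy-Weinberg oracle: carrier probability 1-(1-g*f)^2 vs 1-(1-f)^2
        cfg = _small_cfg(n_cases=2000, gamma={"GENE1": 3.0},
                         enrich_missense_only=False,
                         genotype_missing_rate=0)
        rng = np.random.default_rng(cfg.seed)
        panel = simulate_gene_panel(cfg, rng)
        sites = simulate_site_afs(panel, cfg, rng)
        cohort = simulate_case_cohort(sites, cfg, rng)
        by_key = cohort.by_key()
        g1_common = [s for s in sites if s.gene == "GENE1" and s.is_common]
        rates = []
        for s in g1_common:
            dos = by_key[s.key].dosages
            rates.append((dos > 0).mean())
        expected = [1 - (1 - min(0.5, 3 * s.freq)) ** 2 for s in g1_common]
        null = [1 - (1 - s.freq) ** 2 for s in g1_common]
        assert np.mean(rates) > np.mean(null)
        assert abs(np.mean(rates) - np.mean(expected)) < 0.05

    def test_gamma_below_one_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(gamma={"G": 0.5})

    def test_multiallelic_samples_carry_at_most_two_alt_alleles(self):
        cfg = _small_cfg(multiallelic_rate=0.5, common_sites_per_gene=8)
        rng = np.random.default_rng(cfg.seed)
        panel = simulate_gene_panel(cfg, rng)
        sites = simulate_site_afs(panel, cfg, rng)
        cohort = simulate_case_cohort(sites, cfg, rng)
        by_pos = {}
        for v in cohort.variants:
            by_pos.setdefault((v.chrom, v.pos, v.ref), []).append(v)
        for group in by_pos.values():
            if len(group) > 1:
                total = np.clip(
                    np.stack([g.dosages for g in group]), 0, None
                ).sum(axis=0)
                assert total.max() <= 2


def test_generated_data_flows_through_selection(tmp_path):
    """Self-consumption: simulator output feeds the qualifying module."""
    cfg = _small_cfg(indel_rate=0.3, outside_rate=0.3)
    rng = np.random.default_rng(cfg.seed)
    panel = simulate_gene_panel(cfg, rng)
    sites = simulate_site_afs(panel, cfg, rng)
    ctrl = simulate_control_summary(sites, cfg, rng)
    qs = select_qualifying(ctrl, panel)
    truth = {
        s.key for s in sites
        if s.in_exon and not s.is_indel and "missense_variant" in s.consequences
    }
    selected = {k for keys in qs.genes.values() for k in keys}
    assert selected == truth


def test_calibration_warns_on_few_replicates(caplog):
    cfg = _small_cfg(n_cases=20, n_controls=200, n_genes=2,
                     rare_sites_per_gene=3, common_sites_per_gene=1)
    with caplog.at_level("WARNING"):
        report = run_calibration_experiment(cfg, 5, seed=1)
    assert report.n_replicates == 5
    assert any("replicates" in r.message for r in caplog.records)
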