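"""Synthetic case cohorts and summary-statistic controls with known burden.

The generator emulates the study design the pipeline targets: a clinical case
cohort with per-sample genotypes over a small panel of genes (default 184
cases, 8 genes) and a large population control cohort visible only through
per-site summary statistics (default 56,885 controls), with sites drawn from
a mixture of rare (1e-4..1e-3) and common (1e-2..1e-1) allele frequencies.
Genotypes follow Hardy-Weinberg proportions with per-site independence; a
per-gene enrichment factor gamma >= 1 multiplies allele frequencies in cases
(capped at 0.5), giving a known truth for power and calibration experiments.

Spiked-in indels, multiallelic records, off-exon sites, low-depth sites and
low-QD sites exercise every exclusion rule of the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .controls import ControlSite
from .genes import GeneModel
from .variants import MISSING, CaseCohort, CaseVariant

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the target study: 184 cases against 56,885
    summary-statistic controls over an 8-gene autosomal panel, with mostly
    rare missense sites plus a handful of common ones per gene.
    """

    n_cases: int = 184
    n_controls: int = 56_885
    n_genes: int = 8
    exons_per_gene: tuple[int, int] = (4, 10)
    exon_length: tuple[int, int] = (80, 400)
    intron_length: tuple[int, int] = (200, 2_000)
    rare_sites_per_gene: int = 30
    common_sites_per_gene: int = 5
    rare_freq: tuple[float, float] = (1e-4, 1e-3)
    common_freq: tuple[float, float] = (1e-2, 1e-1)
    missense_fraction: float = 0.7
    gamma: dict[str, float] = field(default_factory=dict)
    enrich_common_only: bool = False
    enrich_missense_only: bool = True
    indel_rate: float = 0.05
    multiallelic_rate: float = 0.05
    outside_rate: float = 0.05
    depth_mean: float = 40.0
    low_depth_fraction: float = 0.05
    low_qd_fraction: float = 0.05
    genotype_missing_rate: float = 0.01
    an_missing_rate: float = 0.01
    pad: int = 5
    include_x_gene: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for g, v in self.gamma.items():
            if v < 1:
                raise ValueError(f"gamma for {g} must be >= 1, got {v}")


@dataclass
class SimSite:
    """One simulated alternate allele with its truth."""

    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    freq: float
    consequences: set[str]
    is_indel: bool = False
    in_exon: bool = True
    is_common: bool = False

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def simulate_gene_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Draw a panel of genes with disjoint coordinate ranges.

    Genes are laid out sequentially along autosomes 1..22 (cycled); exon
    counts and lengths are drawn from the configured ranges.  Deterministic
    given the config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.n_genes < 1:
        raise ValueError("panel count must be >= 1")
    cursor: dict[str, int] = {}
    models = []
    names = [f"GENE{i + 1}" for i in range(config.n_genes)]
    chroms = [str((i % 22) + 1) for i in range(config.n_genes)]
    if config.include_x_gene:
        names.append(f"GENE{config.n_genes + 1}")
        chroms.append("X")
    for gene, chrom in zip(names, chroms):
        start = cursor.get(chrom, 10_000)
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        pos = start
        for _ in range(n_ex):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((pos, pos + length))
            pos += length + int(
                rng.integers(config.intron_length[0], config.intron_length[1] + 1)
            )
        cursor[chrom] = pos + 50_000  # keep gene footprints disjoint
        models.append(GeneModel(gene=gene, chrom=chrom, exons=exons, pad=config.pad))
    return models


def _draw_alleles(rng: np.random.Generator, is_indel: bool) -> tuple[str, str]:
    i, j = rng.choice(4, size=2, replace=False)
    if is_indel:
        return _BASES[i] + _BASES[j], _BASES[i]
    return _BASES[i], _BASES[j]


def simulate_site_afs(
    panel: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SimSite]:
    """Draw per-site allele frequencies and consequence labels for the panel.

    Each gene receives its configured number of rare and common sites at
    positions uniform within the padded exons, each labeled missense with the
    configured probability.  Spike-ins: a fraction of sites are placed beyond
    the pad outside exons, a fraction become indels, and a fraction gain a
    second alternate allele at the same position (a multiallelic record).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sites: list[SimSite] = []
    for m in panel:
        candidates = np.concatenate(
            [np.arange(s, e) for s, e in m.padded_exons]
        )  # 0-based positions inside padded exons
        n_rare, n_common = config.rare_sites_per_gene, config.common_sites_per_gene
        n_total = n_rare + n_common
        chosen = rng.choice(candidates, size=min(n_total, len(candidates)),
                            replace=False)
        is_common = np.zeros(len(chosen), dtype=bool)
        is_common[:n_common] = True
        for p0, common in zip(chosen, is_common):
            lo, hi = config.common_freq if common else config.rare_freq
            freq = float(rng.uniform(lo, hi))
            outside = rng.random() < config.outside_rate
            if outside:
                p0 = m.exons[-1][1] + m.pad + int(rng.integers(1, 50))
            is_indel = rng.random() < config.indel_rate
            ref, alt = _draw_alleles(rng, is_indel)
            cons = (
                {"missense_variant"}
                if rng.random() < config.missense_fraction
                else {"synonymous_variant"}
            )
            site = SimSite(
                gene=m.gene, chrom=m.chrom, pos=int(p0) + 1, ref=ref, alt=alt,
                freq=freq, consequences=cons, is_indel=is_indel,
                in_exon=not outside, is_common=bool(common),
            )
            sites.append(site)
            if not is_indel and rng.random() < config.multiallelic_rate:
                # second ALT at the same position -> multiallelic VCF record
                third = rng.choice([b for b in _BASES if b not in (ref, alt)])
                lo, hi = config.rare_freq
                sites.append(
                    SimSite(
                        gene=m.gene, chrom=m.chrom, pos=site.pos, ref=ref,
                        alt=str(third), freq=float(rng.uniform(lo, hi)),
                        consequences=set(cons), in_exon=site.in_exon,
                    )
                )
    # spiked positions can collide; keep the first of any duplicated key
    seen: set[str] = set()
    unique = []
    for s in sites:
        if s.key not in seen:
            seen.add(s.key)
            unique.append(s)
    unique.sort(key=lambda s: (s.chrom, s.pos, s.alt))
    return unique


def site_gamma(site: SimSite, config: SimulationConfig) -> float:
    """Effective case enrichment factor for one site."""
    g = config.gamma.get(site.gene, 1.0)
    if g == 1.0:
        return 1.0
    if config.enrich_common_only and not site.is_common:
        return 1.0
    if config.enrich_missense_only and "missense_variant" not in site.consequences:
        return 1.0
    return g


def _group_sites(sites: list[SimSite]) -> list[list[SimSite]]:
    groups: dict[tuple[str, int, str], list[SimSite]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.pos, s.ref), []).append(s)
    return list(groups.values())


def simulate_control_summary(
    sites: list[SimSite],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[ControlSite]:
    """Draw gnomAD-style summary statistics under Hardy-Weinberg.

    Per site, with f the allele frequency and n the called controls:
    hom ~ Binomial(n, f^2), het ~ Binomial(n - hom, 2f(1-f)/(1-f^2)),
    ac = het + 2*hom, an = 2n.  A small per-site missingness rate shrinks n
    below the cohort size so AN handling is exercised; within a multiallelic
    group all alleles share one AN draw.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out = []
    for group in _group_sites(sites):
        n_called = config.n_controls - int(
            rng.binomial(config.n_controls, config.an_missing_rate)
        )
        for s in group:
            f = s.freq
            hom = int(rng.binomial(n_called, f * f)) if f > 0 else 0
            p_het = 2 * f * (1 - f) / (1 - f * f) if f > 0 else 0.0
            het = int(rng.binomial(n_called - hom, p_het)) if f > 0 else 0
            out.append(
                ControlSite(
                    chrom=s.chrom, pos=s.pos, ref=s.ref, alt=s.alt,
                    ac=het + 2 * hom, an=2 * n_called, nhomalt=hom,
                    consequences=set(s.consequences),
                )
            )
    out.sort(key=lambda s: (s.chrom, s.pos, s.alt))
    return out


def simulate_control_dosages(
    sites: list[SimSite],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Individual-level control genotypes, (n_controls, n_sites) dosages.

    Used by calibration experiments that need the true number of distinct
    control carriers to benchmark the summation approximation against.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    f = np.array([s.freq for s in sites])
    return rng.binomial(2, f[None, :], size=(config.n_controls, len(sites))).astype(
        np.int8
    )


def summarize_control_dosages(
    sites: list[SimSite], dosages: np.ndarray, an: int
) -> list[ControlSite]:
    """Exact summary statistics of an individual-level control matrix."""
    out = []
    for j, s in enumerate(sites):
        col = dosages[:, j]
        out.append(
            ControlSite(
                chrom=s.chrom, pos=s.pos, ref=s.ref, alt=s.alt,
                ac=int(col.sum()), an=an, nhomalt=int((col == 2).sum()),
                consequences=set(s.consequences),
            )
        )
    return out


def simulate_case_cohort(
    sites: list[SimSite],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CaseCohort:
    """Draw case genotypes under Hardy-Weinberg with per-gene enrichment.

    Per sample and site the alternate dosage follows HW at frequency
    min(0.5, gamma * f).  Within a multiallelic group the two alleles are
    drawn jointly from the categorical allele distribution so every sample
    carries at most two alternate alleles at the position.  Depth and QD
    fields include configurable low-depth and low-QD fractions to exercise
    the site filters; a small genotype missingness rate yields ./. calls.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_cases
    samples = [f"CASE{i + 1:04d}" for i in range(n)]
    variants: list[CaseVariant] = []
    for group in _group_sites(sites):
        freqs = np.array([min(0.5, site_gamma(s, config) * s.freq) for s in group])
        if len(group) == 1:
            dosage = rng.binomial(2, freqs[0], size=n).astype(np.int8)[None, :]
        else:
            # joint draw of two alleles per sample over {ref, alt1, alt2, ...}
            probs = np.concatenate([[max(0.0, 1 - freqs.sum())], freqs])
            probs = probs / probs.sum()
            alleles = rng.choice(len(probs), size=(n, 2), p=probs)
            dosage = np.stack(
                [(alleles == k + 1).sum(axis=1) for k in range(len(group))]
            ).astype(np.int8)
        if config.genotype_missing_rate > 0:
            miss = rng.random(n) < config.genotype_missing_rate
            dosage[:, miss] = MISSING
        low_depth = rng.random() < config.low_depth_fraction
        mean_dp = (
            rng.uniform(2.0, 8.0) if low_depth
            else max(10.5, rng.normal(config.depth_mean, 8.0))
        )
        depths = rng.poisson(mean_dp, size=n).astype(np.int64)
        qd = (
            float(rng.uniform(0.5, 4.0))
            if rng.random() < config.low_qd_fraction
            else float(rng.uniform(4.5, 30.0))
        )
        for k, s in enumerate(group):
            variants.append(
                CaseVariant(
                    chrom=s.chrom, pos=s.pos, ref=s.ref, alt=s.alt,
                    consequences=set(s.consequences), dosages=dosage[k],
                    depths=depths, qd=round(qd, 2),
                )
            )
    variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return CaseCohort(samples=samples, variants=variants)


def write_truth_table(sites: list[SimSite], config: SimulationConfig,
                      path: str) -> None:
    """Write the simulated truth (gene, gamma, per-site frequency) as TSV."""
    with open(path, "w") as fh:
        fh.write("gene\tgamma\tchrom\tpos\tref\talt\tfreq\tconsequence\t"
                 "is_indel\tin_exon\tis_common\n")
        for s in sites:
            fh.write(
                f"{s.gene}\t{config.gamma.get(s.gene, 1.0)}\t{s.chrom}\t{s.pos}\t"
                f"{s.ref}\t{s.alt}\t{s.freq:.6g}\t"
                f"{'&'.join(sorted(s.consequences))}\t"
                f"{int(s.is_indel)}\t{int(s.in_exon)}\t{int(s.is_common)}\n"
            )


def write_simulated_vcf(cohort: CaseCohort, path: str,
                        ann_field: str = "CSQ") -> None:
    """Write the case cohort as VCF, merging same-position alleles into
    multiallelic records so that reading the file exercises biallelic
    expansion."""
    groups: dict[tuple[str, int, str], list[CaseVariant]] = {}
    for v in cohort.variants:
        groups.setdefault((v.chrom, v.pos, v.ref), []).append(v)
    contigs = sorted({v.chrom for v in cohort.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write(
            f'##INFO=<ID={ann_field},Number=.,Type=String,'
            'Description="Consequence annotations. Format: Allele|Consequence">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples) + "\n"
        )
        for (chrom, pos, ref), group in sorted(groups.items()):
            alts = [v.alt for v in group]
            csq = ",".join(
                f"{v.alt}|{'&'.join(sorted(v.consequences))}"
                for v in group if v.consequences
            )
            info = []
            if group[0].qd is not None:
                info.append(f"QD={group[0].qd:g}")
            if csq:
                info.append(f"{ann_field}={csq}")
            cols = [chrom, str(pos), ".", ref, ",".join(alts), ".", "PASS",
                    ";".join(info) or ".", "GT:DP"]
            for i in range(cohort.n_cases):
                ds = [int(v.dosages[i]) for v in group]
                if any(d < 0 for d in ds):
                    gt = "./."
                else:
                    allele_list: list[int] = []
                    for k, d in enumerate(ds):
                        allele_list += [k + 1] * d
                    if len(allele_list) > 2:
                        raise ValueError(
                            f"{chrom}:{pos}: sample {i} carries "
                            f"{len(allele_list)} alternate alleles"
                        )
                    allele_list = [0] * (2 - len(allele_list)) + allele_list
                    gt = "/".join(str(a) for a in allele_list)
                d = group[0].depths
                dp = str(int(d[i])) if d is not None and d[i] >= 0 else "."
                cols.append(f"{gt}:{dp}")
            fh.write("\t".join(cols) + "\n")


def write_control_sites_vcf(sites: list[ControlSite], path: str,
                            ann_field: str = "CSQ") -> None:
    """Write control summaries as a sites-only VCF with AC/AN/nhomalt INFO."""
    groups: dict[tuple[str, int, str], list[ControlSite]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.pos, s.ref), []).append(s)
    contigs = sorted({s.chrom for s in sites})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        fh.write('##INFO=<ID=nhomalt,Number=A,Type=Integer,'
                 'Description="Homozygote count">\n')
        fh.write(
            f'##INFO=<ID={ann_field},Number=.,Type=String,'
            'Description="Consequence annotations. Format: Allele|Consequence">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (chrom, pos, ref), group in sorted(groups.items()):
            ac = ",".join(str(s.ac) for s in group)
            nh = ",".join(str(s.nhomalt) for s in group)
            an = max(s.an for s in group)
            csq = ",".join(
                f"{s.alt}|{'&'.join(sorted(s.consequences))}"
                for s in group if s.consequences
            )
            info = f"AC={ac};AN={an};nhomalt={nh}"
            if csq:
                info += f";{ann_field}={csq}"
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{','.join(s.alt for s in group)}\t.\t"
                f"PASS\t{info}\n"
            )
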