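"""The gene-panel burden model and its fitted results.

`MissenseBurdenModel` bundles the three inputs of the analysis — a case
cohort with genotypes, control summary sites, and the gene panel — together
with the analysis configuration.  `fit()` runs the pipeline (quality filters,
qualifying-variant selection, per-gene collapsing, one-sided Fisher exact
tests, Bonferroni control) and returns a `MissenseBurdenResults` carrying the
per-gene estimates, a results DataFrame and a text summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .consequence import AnnotationSpec
from .controls import ControlSite, load_control_sites
from .counting import (
    DEFAULT_CARRIER_MODE,
    GeneBurdenCounts,
    combine_counts,
    count_case_gene,
    count_control_gene,
)
from .errors import ConsistencyError
from .genes import DEFAULT_PAD, GeneModel, load_gene_models
from .qualify import QualifyingSet, select_qualifying
from .stats import (
    BurdenResult,
    bonferroni_adjust,
    build_tables,
    fisher_one_sided_greater,
    format_p,
    odds_ratio,
)
from .variants import CaseCohort, filter_mean_depth, filter_qd, read_case_vcf

logger = logging.getLogger(__name__)


@dataclass
class BurdenConfig:
    """Tunable analysis parameters.

    min_mean_depth : reads; sites with lower mean DP are dropped (>= kept).
    qd_filter / min_qd : optional strict QD cutoff (replication-cohort QC).
    pad : bp of exon flank for region restriction.
    carrier_mode : control carrier approximation (see `counting`).
    allele_denominator : "2n" or "an" control chromosome totals.
    alpha : family-wise significance level before Bonferroni division.
    """

    min_mean_depth: float = 10.0
    qd_filter: bool = False
    min_qd: float = 4.0
    pad: int = DEFAULT_PAD
    carrier_mode: str = DEFAULT_CARRIER_MODE
    allele_denominator: str = "2n"
    alpha: float = 0.05
    autosome_only: bool = True
    annotation: AnnotationSpec = field(default_factory=AnnotationSpec)


def run_burden(
    case_counts: dict[str, dict],
    control_counts: dict[str, dict],
    config: BurdenConfig | None = None,
) -> list[BurdenResult]:
    """Test every panel gene for case enrichment.

    ``case_counts`` and ``control_counts`` map gene -> the per-side count
    dicts produced by the counting module; both must cover the same panel.
    m for Bonferroni is the panel size of this run.
    """
    config = config or BurdenConfig()
    only_case = set(case_counts) - set(control_counts)
    only_ctrl = set(control_counts) - set(case_counts)
    if only_case or only_ctrl:
        raise ConsistencyError(
            f"genes present on one side only: case-only={sorted(only_case)} "
            f"control-only={sorted(only_ctrl)}"
        )
    m = len(case_counts)
    results = []
    for gene in case_counts:
        counts = combine_counts(case_counts[gene], control_counts[gene])
        subj_t, alle_t = build_tables(counts, config.allele_denominator)
        p_s = fisher_one_sided_greater(subj_t)
        p_a = fisher_one_sided_greater(alle_t)
        or_s, or_s_corr = odds_ratio(subj_t)
        or_a, or_a_corr = odds_ratio(alle_t)
        p_s_cor, thresh = bonferroni_adjust(p_s, m, config.alpha)
        p_a_cor, _ = bonferroni_adjust(p_a, m, config.alpha)
        results.append(
            BurdenResult(
                gene=gene,
                p_subjects=p_s,
                p_alleles=p_a,
                or_subjects=or_s,
                or_alleles=or_a,
                or_subjects_corrected=or_s_corr,
                or_alleles_corrected=or_a_corr,
                p_threshold=thresh,
                p_subjects_corrected=p_s_cor,
                p_alleles_corrected=p_a_cor,
                significant_subjects=p_s < thresh,
                significant_alleles=p_a < thresh,
            )
        )
    return results


class MissenseBurdenModel:
    """Gene-based missense burden test of a case cohort vs summary controls.

    Parameters
    ----------
    cohort : CaseCohort
        Case samples with normalized biallelic variants.
    control_sites : list of ControlSite
        Summary-statistic control sites (AC/AN/nhomalt).
    gene_models : list of GeneModel
        The gene panel; every gene yields a result row (genes without
        qualifying variants keep zero counts so the Bonferroni denominator
        equals the panel size).
    n_controls : int
        Control cohort size (the subject-table denominator).
    config : BurdenConfig, optional
    """

    def __init__(
        self,
        cohort: CaseCohort,
        control_sites: list[ControlSite],
        gene_models: list[GeneModel],
        n_controls: int,
        config: BurdenConfig | None = None,
    ) -> None:
        self.config = config or BurdenConfig()
        for g in gene_models:
            g.pad = self.config.pad
        self.gene_models = gene_models
        self.cohort = cohort
        self.control_sites = control_sites
        self.n_controls = int(n_controls)

    @classmethod
    def from_files(
        cls,
        case_vcf: str,
        control_path: str,
        gene_path: str,
        n_controls: int,
        config: BurdenConfig | None = None,
    ) -> "MissenseBurdenModel":
        """Build the model from a case VCF, control sites file and gene file."""
        config = config or BurdenConfig()
        models = load_gene_models(
            gene_path, pad=config.pad, autosome_only=config.autosome_only
        )
        regions = [(m.chrom, *m.span) for m in models]
        cohort = read_case_vcf(case_vcf, regions=regions, ann_spec=config.annotation)
        sites = load_control_sites(control_path, ann_spec=config.annotation)
        return cls(cohort, sites, models, n_controls, config)

    def fit(self) -> "MissenseBurdenResults":
        """Run filters, qualifying selection, collapsing and the tests."""
        cfg = self.config
        cohort = filter_mean_depth(self.cohort, cfg.min_mean_depth)
        cohort = filter_qd(cohort, cfg.min_qd, enabled=cfg.qd_filter)
        case_qs = select_qualifying(cohort.variants, self.gene_models)
        ctrl_qs = select_qualifying(self.control_sites, self.gene_models)
        ctrl_by_key = {s.key: s for s in self.control_sites}

        case_counts, ctrl_counts = {}, {}
        for m in self.gene_models:
            gene = m.gene
            case_counts[gene] = count_case_gene(cohort, gene, case_qs[gene])
            sites = [ctrl_by_key[k] for k in ctrl_qs[gene]]
            ctrl_counts[gene] = count_control_gene(
                sites, gene, self.n_controls, cfg.carrier_mode
            )
        results = run_burden(case_counts, ctrl_counts, cfg)
        counts = {
            g: combine_counts(case_counts[g], ctrl_counts[g]) for g in case_counts
        }
        return MissenseBurdenResults(self, results, counts, case_qs, ctrl_qs)


class MissenseBurdenResults:
    """Fitted per-gene burden results with a results table and summary."""

    def __init__(
        self,
        model: MissenseBurdenModel,
        results: list[BurdenResult],
        counts: dict[str, GeneBurdenCounts],
        case_qualifying: QualifyingSet,
        control_qualifying: QualifyingSet,
    ) -> None:
        self.model = model
        self.results = results
        self.counts = counts
        self.case_qualifying = case_qualifying
        self.control_qualifying = control_qualifying

    @property
    def m_genes(self) -> int:
        return len(self.results)

    @property
    def frame(self) -> pd.DataFrame:
        """Results table mirroring the discovery-table column order."""
        rows = []
        for r in self.results:
            c = self.counts[r.gene]
            gene_len = next(
                (g.length_bp for g in self.model.gene_models if g.gene == r.gene),
                None,
            )
            rows.append(
                {
                    "gene": r.gene,
                    "gene_length_bp": gene_len,
                    "case_het": c.n_case_het,
                    "case_hom": c.n_case_hom,
                    "case_carriers": c.n_case_carriers,
                    "control_count": c.control_carrier_est,
                    "case_allele_count": c.case_ac,
                    "control_allele_count": c.control_ac,
                    "p_subjects": r.p_subjects,
                    "p_alleles": r.p_alleles,
                    "or_subjects": round(r.or_subjects, 3),
                    "or_alleles": round(r.or_alleles, 3),
                    "p_subjects_cor": r.p_subjects_corrected,
                    "p_alleles_cor": r.p_alleles_corrected,
                    "p_subjects_text": format_p(r.p_subjects),
                    "p_alleles_text": format_p(r.p_alleles),
                    "significant": r.significant_subjects or r.significant_alleles,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        """Human-readable per-gene summary table."""
        cfg = self.model.config
        lines = [
            "Gene-based missense burden test (one-sided Fisher exact)",
            f"cases n={self.model.cohort.n_cases}  "
            f"controls n={self.model.n_controls}  genes m={self.m_genes}",
            f"carrier mode={cfg.carrier_mode}  "
            f"alpha={cfg.alpha}  threshold={cfg.alpha / self.m_genes:.3g}",
            "-" * 78,
            f"{'gene':<10}{'carriers':>9}{'case_ac':>9}{'ctrl_est':>10}"
            f"{'ctrl_ac':>9}{'p_subj':>11}{'p_allele':>11}{'sig':>5}",
        ]
        for r in self.results:
            c = self.counts[r.gene]
            sig = "*" if (r.significant_subjects or r.significant_alleles) else ""
            lines.append(
                f"{r.gene:<10}{c.n_case_carriers:>9}{c.case_ac:>9}"
                f"{c.control_carrier_est:>10}{c.control_ac:>9}"
                f"{format_p(r.p_subjects):>11}{format_p(r.p_alleles):>11}{sig:>5}"
            )
        return "\n".join(lines)


def write_results(results: "MissenseBurdenResults", path: str) -> None:
    """Write the fitted results table as TSV."""
    results.to_tsv(path)
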