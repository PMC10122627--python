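"""Monte-Carlo calibration of the burden test on synthetic cohorts.

Two experiments validate the statistical behaviour of the pipeline:

* under the null (gamma = 1 everywhere) the empirical type-I error of the
  subject and allele tests at a nominal alpha, for the exact control carrier
  count and for both summation approximations — the approximations inflate
  the control success count and can only make the upper-tail p larger, so
  they must never be anti-conservative;
* under enrichment (gamma > 1 on one gene) the power to flag that gene, and
  only that gene, at the Bonferroni threshold.

Each replicate runs the actual pipeline components on in-memory objects:
site simulation, Hardy-Weinberg genotype draws, qualifying-variant selection,
per-gene collapsing and the Fisher tests.  VCF serialisation is exercised
elsewhere (round-trip tests and the end-to-end demo), not repeated here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .counting import count_case_gene, estimate_control_carriers
from .qualify import select_qualifying
from .simulate import (
    SimulationConfig,
    simulate_case_cohort,
    simulate_control_dosages,
    simulate_gene_panel,
    simulate_site_afs,
    summarize_control_dosages,
)
from .stats import fisher_one_sided_greater_many

logger = logging.getLogger(__name__)


@dataclass
class CalibrationReport:
    """Empirical error rates of the burden test over simulated replicates."""

    n_replicates: int
    n_tests: int
    alpha: float
    seed: int
    type1_subjects_exact: float
    type1_subjects_sum_ac: float
    type1_subjects_sum_ac_minus_hom: float
    type1_alleles: float
    mc_se: float
    n_anticonservative_sum_ac: int
    n_anticonservative_sum_ac_minus_hom: int
    enriched_gene: str | None = None
    power_enriched: float | None = None
    power_exclusive: float | None = None
    bonferroni_threshold: float | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"calibration over {self.n_replicates} replicates "
            f"({self.n_tests} gene-tests), alpha={self.alpha}, seed={self.seed}",
            f"  type-I subjects: exact={self.type1_subjects_exact:.4f}  "
            f"sum_ac={self.type1_subjects_sum_ac:.4f}  "
            f"sum_ac_minus_hom={self.type1_subjects_sum_ac_minus_hom:.4f}",
            f"  type-I alleles:  {self.type1_alleles:.4f}   "
            f"(MC SE {self.mc_se:.4f})",
            f"  anti-conservative approximations: "
            f"sum_ac={self.n_anticonservative_sum_ac}, "
            f"sum_ac_minus_hom={self.n_anticonservative_sum_ac_minus_hom}",
        ]
        if self.enriched_gene is not None:
            lines.append(
                f"  power on {self.enriched_gene} at threshold "
                f"{self.bonferroni_threshold:.3g}: "
                f"{self.power_enriched:.3f} (exclusive {self.power_exclusive:.3f})"
            )
        return "\n".join(lines)


def _replicate_counts(config: SimulationConfig, rng: np.random.Generator):
    """One replicate: simulate, qualify, collapse.  Returns per-gene counts."""
    panel = simulate_gene_panel(config, rng)
    sites = simulate_site_afs(panel, config, rng)
    ctrl_dos = simulate_control_dosages(sites, config, rng)
    ctrl_sites = summarize_control_dosages(sites, ctrl_dos, 2 * config.n_controls)
    cohort = simulate_case_cohort(sites, config, rng)

    case_qs = select_qualifying(cohort.variants, panel)
    ctrl_qs = select_qualifying(ctrl_sites, panel)
    ctrl_by_key = {s.key: s for s in ctrl_sites}
    site_col = {s.key: j for j, s in enumerate(sites)}

    out = []
    for m in panel:
        cc = count_case_gene(cohort, m.gene, case_qs[m.gene])
        gsites = [ctrl_by_key[k] for k in ctrl_qs[m.gene]]
        cols = [site_col[k] for k in ctrl_qs[m.gene]]
        if cols:
            sub = ctrl_dos[:, cols]
            exact_carriers = int((sub.sum(axis=1) > 0).sum())
        else:
            exact_carriers = 0
        out.append(
            {
                "gene": m.gene,
                "case_carriers": cc["n_case_carriers"],
                "case_ac": cc["case_ac"],
                "ctrl_exact": exact_carriers,
                "ctrl_sum_ac": estimate_control_carriers(
                    gsites, config.n_controls, "sum_ac"
                ),
                "ctrl_sum_ac_minus_hom": estimate_control_carriers(
                    gsites, config.n_controls, "sum_ac_minus_hom"
                ),
                "ctrl_ac": sum(s.ac for s in gsites),
            }
        )
    return out


def run_calibration_experiment(
    config: SimulationConfig,
    n_replicates: int,
    alpha: float = 0.05,
    seed: int | None = None,
) -> CalibrationReport:
    """Estimate type-I error (and power when gamma > 1) by simulation.

    Under gamma = 1 the reported type-I errors are the pooled fraction of
    per-gene tests with p < alpha.  When the config enriches one gene, power
    is the fraction of replicates in which that gene's subject test falls
    below the Bonferroni threshold alpha / m, and exclusive power additionally
    requires every other gene to stay above it.
    """
    if n_replicates < 100:
        logger.warning(
            "only %d replicates: Monte-Carlo confidence intervals will be wide",
            n_replicates,
        )
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    enriched = [g for g, v in config.gamma.items() if v > 1]
    enriched_gene = enriched[0] if enriched else None

    names: list[str] = []
    rows = {k: [] for k in ("case_carriers", "case_ac", "ctrl_exact",
                            "ctrl_sum_ac", "ctrl_sum_ac_minus_hom", "ctrl_ac")}
    for _ in range(n_replicates):
        rep = _replicate_counts(config, rng)
        for r in rep:
            names.append(r["gene"])
            for k in rows:
                rows[k].append(r[k])
    arr = {k: np.array(v, dtype=np.int64) for k, v in rows.items()}
    names_a = np.array(names)
    n_ca, n_co = config.n_cases, config.n_controls

    def subj_p(ctrl_succ: np.ndarray) -> np.ndarray:
        return fisher_one_sided_greater_many(
            arr["case_carriers"], n_ca - arr["case_carriers"],
            ctrl_succ, n_co - ctrl_succ,
        )

    p_exact = subj_p(arr["ctrl_exact"])
    p_sum_ac = subj_p(arr["ctrl_sum_ac"])
    p_sum_ac_mh = subj_p(arr["ctrl_sum_ac_minus_hom"])
    p_alleles = fisher_one_sided_greater_many(
        arr["case_ac"], 2 * n_ca - arr["case_ac"],
        arr["ctrl_ac"], 2 * n_co - arr["ctrl_ac"],
    )

    null_mask = (
        names_a != enriched_gene if enriched_gene else np.ones(len(names_a), bool)
    )
    n_null = int(null_mask.sum())
    report = CalibrationReport(
        n_replicates=n_replicates,
        n_tests=n_null,
        alpha=alpha,
        seed=seed,
        type1_subjects_exact=float((p_exact[null_mask] < alpha).mean()),
        type1_subjects_sum_ac=float((p_sum_ac[null_mask] < alpha).mean()),
        type1_subjects_sum_ac_minus_hom=float(
            (p_sum_ac_mh[null_mask] < alpha).mean()
        ),
        type1_alleles=float(
            (p_alleles[null_mask][~np.isnan(p_alleles[null_mask])] < alpha).mean()
        ),
        mc_se=float(np.sqrt(alpha * (1 - alpha) / n_null)),
        n_anticonservative_sum_ac=int((p_sum_ac < p_exact - 1e-12).sum()),
        n_anticonservative_sum_ac_minus_hom=int(
            (p_sum_ac_mh < p_exact - 1e-12).sum()
        ),
    )
    if enriched_gene:
        m = config.n_genes
        thresh = alpha / m
        p_mat = p_sum_ac_mh.reshape(n_replicates, m)
        gene_order = names_a.reshape(n_replicates, m)[0]
        idx = int(np.where(gene_order == enriched_gene)[0][0])
        hit = p_mat[:, idx] < thresh
        others = np.delete(p_mat, idx, axis=1)
        report.enriched_gene = enriched_gene
        report.bonferroni_threshold = thresh
        report.power_enriched = float(hit.mean())
        report.power_exclusive = float((hit & (others >= thresh).all(axis=1)).mean())
    return report
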