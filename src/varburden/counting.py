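"""Per-gene collapsing of qualifying variants into case and control counts.

Cases have genotypes, so carrier and allele counts are exact.  Controls are
known only through per-site summary statistics, so the number of control
carriers is approximated by summing per-site allele counts across the gene
(optionally subtracting homozygote counts so a homozygote is counted once).
The summation over-counts individuals carrying several qualifying variants in
the same gene; it therefore overestimates control carriers, which makes the
downstream case-enrichment test conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .controls import ControlSite
from .variants import CaseCohort

logger = logging.getLogger(__name__)

CARRIER_MODES = ("sum_ac", "sum_ac_minus_hom")
DEFAULT_CARRIER_MODE = "sum_ac_minus_hom"


@dataclass
class GeneBurdenCounts:
    """Collapsed per-gene counts for one burden-test row.

    ``n_case_het`` / ``n_case_hom`` count cases with at least one het /
    at least one hom qualifying genotype; a case carrying both contributes to
    each, so the two columns may sum to more than ``n_case_carriers``, the
    number of distinct carriers.
    """

    gene: str
    n_case_het: int
    n_case_hom: int
    n_case_carriers: int
    case_ac: int
    control_carrier_est: int
    control_ac: int
    n_cases: int
    n_controls: int
    control_an_max: int = 0  # largest per-site AN seen in the gene (0 = none)

    def __post_init__(self) -> None:
        ok = (
            self.n_case_carriers <= self.n_cases
            and self.n_case_carriers <= self.case_ac
        )
        ok = ok and max(self.n_case_het, self.n_case_hom) <= self.n_case_carriers
        ok = ok and self.n_case_carriers <= self.n_case_het + self.n_case_hom
        ok = ok and self.control_carrier_est <= min(self.n_controls, self.control_ac)
        if not ok:
            raise ValueError(f"inconsistent burden counts for gene {self.gene}: {self}")


def count_case_gene(
    cohort: CaseCohort, gene: str, keys: list[str]
) -> dict[str, int]:
    """Collapse the case dosage matrix over a gene's qualifying keys.

    Missing genotypes count as homozygous reference; the case denominator is
    the full cohort size at every site (matching the fixed-denominator
    treatment forced by summary-statistic controls).  Keys absent from the
    cohort contribute nothing.
    """
    dm = cohort.dosage_matrix(keys)  # (n_samples, n_keys), -1 = missing
    dm = np.where(dm < 0, 0, dm)
    het = int(((dm == 1).any(axis=1)).sum())
    hom = int(((dm == 2).any(axis=1)).sum())
    carriers = int((dm.sum(axis=1) > 0).sum())
    case_ac = int(dm.sum())
    return {
        "gene": gene,
        "n_case_het": het,
        "n_case_hom": hom,
        "n_case_carriers": carriers,
        "case_ac": case_ac,
        "n_cases": cohort.n_cases,
    }


def estimate_control_carriers(
    sites: list[ControlSite], n_controls: int, mode: str = DEFAULT_CARRIER_MODE
) -> int:
    """Approximate control carriers from summary statistics.

    ``sum_ac`` sums per-site allele counts; ``sum_ac_minus_hom`` subtracts
    homozygote counts so each homozygote contributes one carrier.  Both
    overestimate the true number of distinct carriers whenever an individual
    carries several qualifying variants in the gene; the estimate is capped at
    the cohort size.
    """
    if n_controls <= 0:
        raise ValueError("n_controls must be positive")
    if mode not in CARRIER_MODES:
        raise ValueError(f"unknown carrier mode {mode!r}; use one of {CARRIER_MODES}")
    if mode == "sum_ac":
        est = sum(s.ac for s in sites)
    else:
        est = sum(s.ac - s.nhomalt for s in sites)
    return min(est, n_controls)


def count_control_gene(
    sites: list[ControlSite],
    gene: str,
    n_controls: int,
    mode: str = DEFAULT_CARRIER_MODE,
) -> dict[str, int]:
    """Collapse a gene's qualifying control sites into summary counts."""
    return {
        "gene": gene,
        "control_ac": sum(s.ac for s in sites),
        "control_carrier_est": estimate_control_carriers(sites, n_controls, mode),
        "n_controls": n_controls,
        "control_an_max": max((s.an for s in sites), default=0),
    }


def combine_counts(case: dict[str, int], control: dict[str, int]) -> GeneBurdenCounts:
    """Merge the case and control halves of one gene's counts."""
    if case["gene"] != control["gene"]:
        raise ValueError(f"gene mismatch: {case['gene']} vs {control['gene']}")
    return GeneBurdenCounts(**{**case, **control, "gene": case["gene"]})
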