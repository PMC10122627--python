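"""Contingency tables, one-sided Fisher exact tests and Bonferroni control.

The burden test asks whether cases carry an excess of qualifying variants
relative to controls, per gene, on two 2x2 tables:

* subjects: carriers vs non-carriers, with the fixed cohort sizes as
  denominators (control carriers are the summation estimate);
* alleles:  summed alternate alleles vs the remaining 2N alleles.

The one-sided p is the exact hypergeometric upper tail
P(X >= a | margins), i.e. enrichment in cases; depletion is never flagged.
Family-wise error is controlled by Bonferroni over the genes in the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .counting import GeneBurdenCounts
from .errors import ConsistencyError, UntestableGeneError

#: p-values below this are displayed as an inequality, as is conventional
#: for exact tests reported via R (.Machine$double.eps).
DISPLAY_FLOOR = 2.2e-16

ALLELE_DENOMINATORS = ("2n", "an")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a,b = case successes/failures; c,d = control ones."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConsistencyError(f"negative cell in table {self}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


def fisher_one_sided_greater(t: ContingencyTable) -> float:
    """Exact upper-tail p for case enrichment.

    With N = a+b+c+d, K = a+c and n = a+b, returns P(X >= a) for
    X ~ Hypergeometric(N, K, n).  Computed via the survival function in
    log-space (scipy), floored only by floating-point underflow.
    """
    a, b, c, d = t.cells
    n = a + b
    if n == 0:
        raise UntestableGeneError("case margin is zero; table untestable")
    N = a + b + c + d
    K = a + c
    return float(hypergeom.sf(a - 1, N, K, n))


def fisher_one_sided_greater_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    """Vectorised upper-tail Fisher p over arrays of table cells.

    Tables with a negative cell (e.g. an allele count exceeding the assumed
    chromosome total, possible for heavily mutated genes) yield NaN rather
    than an error, so simulation sweeps can mask them out.
    """
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    if np.any(a + b == 0):
        raise UntestableGeneError("case margin is zero; table untestable")
    valid = (a >= 0) & (b >= 0) & (c >= 0) & (d >= 0)
    out = np.full(a.shape, np.nan)
    av, bv, cv, dv = a[valid], b[valid], c[valid], d[valid]
    out[valid] = hypergeom.sf(av - 1, av + bv + cv + dv, av + cv, av + bv)
    return out


def odds_ratio(t: ContingencyTable) -> tuple[float, bool]:
    """(a*d)/(b*c); zero cells get the Haldane-Anscombe +0.5 correction.

    Returns (ratio, corrected) where ``corrected`` flags that the continuity
    correction was applied.
    """
    a, b, c, d = (float(x) for x in t.cells)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return a * d / (b * c), True
    return a * d / (b * c), False


def bonferroni_adjust(
    p: float, m: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Return (corrected p = min(1, m*p), family-wise threshold alpha/m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return min(1.0, m * p), alpha / m


def build_tables(
    counts: GeneBurdenCounts, allele_denominator: str = "2n"
) -> tuple[ContingencyTable, ContingencyTable]:
    """Build the subject and allele tables for one gene.

    Subjects: carriers vs the rest of each cohort.  Alleles: summed alternate
    alleles vs the remaining chromosomes; the control chromosome total is
    2*n_controls (``"2n"``, the default) or the gene's largest per-site AN
    (``"an"``), matching summary extracts in which not every control is
    called at every site.  Negative cells raise a consistency error naming
    the gene.
    """
    if allele_denominator not in ALLELE_DENOMINATORS:
        raise ValueError(f"allele_denominator must be one of {ALLELE_DENOMINATORS}")
    try:
        subjects = ContingencyTable(
            counts.n_case_carriers,
            counts.n_cases - counts.n_case_carriers,
            counts.control_carrier_est,
            counts.n_controls - counts.control_carrier_est,
        )
        control_chroms = 2 * counts.n_controls
        if allele_denominator == "an" and counts.control_an_max > 0:
            control_chroms = counts.control_an_max
        alleles = ContingencyTable(
            counts.case_ac,
            2 * counts.n_cases - counts.case_ac,
            counts.control_ac,
            control_chroms - counts.control_ac,
        )
    except ConsistencyError as exc:
        raise ConsistencyError(f"gene {counts.gene}: {exc}") from exc
    return subjects, alleles


@dataclass
class BurdenResult:
    """Per-gene test outputs mirroring one results-table row."""

    gene: str
    p_subjects: float
    p_alleles: float
    or_subjects: float
    or_alleles: float
    or_subjects_corrected: bool
    or_alleles_corrected: bool
    p_threshold: float
    p_subjects_corrected: float
    p_alleles_corrected: float
    significant_subjects: bool
    significant_alleles: bool


def format_p(p: float) -> str:
    """Display form: 3 significant figures, floored at the display limit."""
    if p < DISPLAY_FLOOR:
        return "< 2.2e-16"
    return f"{p:.3g}"
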