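"""Qualifying-variant selection and the per-gene variant group ("SNP") file.

A variant qualifies for a gene iff it is a single-nucleotide variant, lies
inside the gene's padded exon intervals, and carries the missense_variant
consequence.  Indels never qualify: they are excluded because of their higher
artefact rate across heterogeneous sequencing platforms.  On the control side
the same rule is applied across the entire gene, not restricted to positions
seen in cases, so both cohorts contribute all their missense variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .consequence import MISSENSE
from .controls import ControlSite
from .errors import SnpFileError
from .genes import GeneModel
from .variants import CaseVariant

logger = logging.getLogger(__name__)


def parse_key(key: str) -> tuple[str, int, str, str]:
    """Split a ``chrom:pos:ref:alt`` variant key (pos 1-based)."""
    parts = key.split(":")
    if len(parts) != 4:
        raise SnpFileError(f"malformed variant key: {key!r}")
    chrom, pos, ref, alt = parts
    return chrom, int(pos), ref, alt


@dataclass
class QualifyingSet:
    """Per-gene ordered sets of qualifying variant keys."""

    genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, keys in self.genes.items():
            if len(set(keys)) != len(keys):
                raise SnpFileError(f"duplicate variant keys for gene {gene}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, QualifyingSet) and self.genes == other.genes

    def __getitem__(self, gene: str) -> list[str]:
        return self.genes[gene]

    def add(self, gene: str, key: str) -> None:
        keys = self.genes.setdefault(gene, [])
        if key not in keys:
            keys.append(key)


def select_qualifying(
    variants: list[CaseVariant] | list[ControlSite],
    models: list[GeneModel],
) -> QualifyingSet:
    """Select qualifying missense SNVs per gene.

    Works identically for case variants and control sites (both expose
    position, alleles and a consequence set).  A variant falling inside the
    padded exons of more than one gene is assigned to each, with a warning.
    Genes with no qualifying variant still appear, with an empty list, so the
    panel size (the multiple-testing denominator) is preserved downstream.
    """
    qs = QualifyingSet({m.gene: [] for m in models})
    for v in variants:
        if not v.is_snv:
            continue
        if MISSENSE not in v.consequences:
            continue
        hits = [m for m in models if m.contains(v.chrom, v.pos)]
        if len(hits) > 1:
            logger.warning(
                "variant %s overlaps %d genes (%s); assigned to all",
                v.key, len(hits), ",".join(m.gene for m in hits),
            )
        for m in hits:
            qs.add(m.gene, v.key)
    return qs


def write_snp_file(qs: QualifyingSet, path: str) -> None:
    """Write one line per gene: symbol, tab, comma-separated variant keys."""
    with open(path, "w") as fh:
        for gene, keys in qs.genes.items():
            fh.write(f"{gene}\t{','.join(keys)}\n")


def read_snp_file(path: str) -> QualifyingSet:
    """Read a variant group file; duplicate gene lines are an error."""
    genes: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                gene, keys_s = line.split("\t")
            except ValueError as exc:
                raise SnpFileError(f"{path}:{lineno}: expected 2 columns") from exc
            if gene in genes:
                raise SnpFileError(f"{path}:{lineno}: duplicate gene line {gene}")
            keys = [k for k in keys_s.split(",") if k]
            for k in keys:
                parse_key(k)  # validate
            genes[gene] = keys
    return QualifyingSet(genes)
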