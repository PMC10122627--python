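"""Gene exon models: loading, interval merging and flank padding.

A gene is represented by its coding exons as 0-based half-open intervals on a
single chromosome.  Variants are later restricted to the exons extended by a
small flank (default 5 bp) so that consequences annotated at exon boundaries
(e.g. splice-region missense calls) are not lost to off-by-a-few coordinate
differences between annotation sources.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import pandas as pd

from .errors import GeneModelError

logger = logging.getLogger(__name__)

#: chromosome names regarded as autosomal (with or without a "chr" prefix)
_AUTOSOMES = {str(i) for i in range(1, 23)}

DEFAULT_PAD = 5


def _is_autosome(chrom: str) -> bool:
    return chrom.removeprefix("chr") in _AUTOSOMES


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort 0-based half-open intervals and merge overlapping or abutting ones."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if start > end:
            raise GeneModelError(f"interval start {start} > end {end}")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class GeneModel:
    """A named gene with merged exon intervals used for region restriction.

    Parameters
    ----------
    gene : str
        Gene symbol.
    chrom : str
        Chromosome name, as spelled in the input files.
    exons : list of (int, int)
        0-based half-open exon intervals; merged and sorted on construction.
    pad : int
        Flank width in bp added to each exon side before region tests.
    """

    gene: str
    chrom: str
    exons: list[tuple[int, int]]
    pad: int = DEFAULT_PAD
    length_bp: int | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.exons:
            raise GeneModelError(f"gene {self.gene} has no exons")
        if self.pad < 0:
            raise GeneModelError(f"gene {self.gene}: pad must be >= 0")
        self.exons = merge_intervals(list(self.exons))
        if self.length_bp is None:
            self.length_bp = sum(e - s for s, e in self.exons)

    @property
    def padded_exons(self) -> list[tuple[int, int]]:
        """Exons extended by ``pad`` on both sides, re-merged, floored at 0."""
        return merge_intervals(
            [(max(0, s - self.pad), e + self.pad) for s, e in self.exons]
        )

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 1-based position ``pos`` falls inside the padded exons."""
        if chrom != self.chrom:
            return False
        p0 = pos - 1
        padded = self.padded_exons
        i = bisect_right([s for s, _ in padded], p0) - 1
        return i >= 0 and p0 < padded[i][1]

    @property
    def span(self) -> tuple[int, int]:
        """(start, end) of the padded gene footprint, 0-based half-open."""
        padded = self.padded_exons
        return padded[0][0], padded[-1][1]


def pad_exons(model: GeneModel) -> list[tuple[int, int]]:
    """Return the model's padded, re-merged exon intervals."""
    return model.padded_exons


def load_gene_models(
    path: str,
    fmt: str | None = None,
    pad: int = DEFAULT_PAD,
    autosome_only: bool = True,
) -> list[GeneModel]:
    """Read gene models from a BED or exon TSV file.

    BED rows are 0-based half-open with the gene symbol in column 4; exon TSV
    carries columns gene, chrom, start, end (0-based half-open).  One
    :class:`GeneModel` is produced per distinct gene symbol with its exons
    merged.  Genes on non-autosomal chromosomes are excluded (with a warning)
    when ``autosome_only`` is on, mirroring collapsing frameworks that test
    autosomes only.
    """
    if fmt is None:
        fmt = "bed" if str(path).endswith((".bed", ".bed.gz")) else "exon-tsv"
    if fmt == "bed":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "gene"],
            dtype={"chrom": str},
        )
    elif fmt == "exon-tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = {"gene", "chrom", "start", "end"} - set(df.columns)
        if missing:
            raise GeneModelError(f"exon TSV lacks columns: {sorted(missing)}")
    else:
        raise GeneModelError(f"unknown gene model format: {fmt!r}")

    models: list[GeneModel] = []
    for gene, grp in df.groupby("gene", sort=False):
        chroms = grp["chrom"].unique()
        if len(chroms) > 1:
            raise GeneModelError(f"gene {gene} spans chromosomes {list(chroms)}")
        chrom = str(chroms[0])
        if autosome_only and not _is_autosome(chrom):
            logger.warning(
                "gene %s on non-autosomal chromosome %s excluded", gene, chrom
            )
            continue
        exons = list(zip(grp["start"].astype(int), grp["end"].astype(int)))
        models.append(GeneModel(gene=str(gene), chrom=chrom, exons=exons, pad=pad))
    return models


def write_gene_bed(models: list[GeneModel], path: str) -> None:
    """Write gene models as BED (0-based half-open, column 4 = gene symbol)."""
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                fh.write(f"{m.chrom}\t{s}\t{e}\t{m.gene}\n")
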