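"""Case-cohort variant input: VCF reading, multiallelic splitting, filters.

The case side of a burden analysis needs per-sample genotypes.  Records are
normalised to one alternate allele each, with per-sample alternate-allele
dosages in {0, 1, 2} (-1 = missing genotype).  Two site-quality filters mirror
common exome QC: a mean-depth floor (mean DP over samples with a depth value)
and an optional strict quality-by-depth (QD) cutoff.

Indel left-alignment is deliberately not performed: indels are excluded from
the analysis downstream, so the only representation normalisation the pipeline
depends on is biallelic expansion and exact-duplicate removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .consequence import AnnotationSpec, parse_consequences
from .errors import VcfFormatError

logger = logging.getLogger(__name__)

MISSING = -1  # dosage / depth sentinel


@dataclass
class RawRecord:
    """One VCF record before multiallelic splitting.

    ``genotypes`` holds per-sample tuples of allele indices (0 = REF, k = k-th
    ALT, -1 = uncalled).  ``depths`` is a per-sample DP vector (-1 = missing)
    or None when the VCF carries no DP.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[str]
    genotypes: list[tuple[int, ...]]
    depths: np.ndarray | None = None
    qd: float | None = None
    annotation: str | None = None


@dataclass
class CaseVariant:
    """A normalized biallelic site with per-sample alternate-allele dosages."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    consequences: set[str] = field(default_factory=set)
    dosages: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    depths: np.ndarray | None = None
    qd: float | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.ref == self.alt:
            raise VcfFormatError(
                f"{self.chrom}:{self.pos} REF equals ALT ({self.ref})"
            )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def mean_depth(self) -> float | None:
        """Mean DP over samples with a depth value; None when unassessable."""
        if self.depths is None:
            return None
        d = np.asarray(self.depths)
        d = d[d >= 0]
        if d.size == 0:
            return None
        return float(d.mean())

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )


@dataclass
class CaseCohort:
    """An ordered set of case samples and their normalized variants."""

    samples: list[str]
    variants: list[CaseVariant] = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return len(self.samples)

    def __post_init__(self) -> None:
        for v in self.variants:
            if len(v.dosages) != self.n_cases:
                raise VcfFormatError(
                    f"variant {v.key} has {len(v.dosages)} dosages for "
                    f"{self.n_cases} samples"
                )

    def by_key(self) -> dict[str, CaseVariant]:
        return {v.key: v for v in self.variants}

    def dosage_matrix(self, keys: list[str]) -> np.ndarray:
        """(n_samples, n_keys) dosage matrix; absent keys contribute zeros."""
        index = self.by_key()
        out = np.zeros((self.n_cases, len(keys)), dtype=np.int8)
        for j, k in enumerate(keys):
            v = index.get(k)
            if v is not None:
                out[:, j] = v.dosages
        return out


def split_multiallelic(
    record: RawRecord, ann_spec: AnnotationSpec = AnnotationSpec()
) -> list[CaseVariant]:
    """Expand a raw record into one CaseVariant per alternate allele.

    The dosage of output k for a sample is the number of that sample's called
    genotype alleles equal to ALT k; a sample with no called allele is missing
    (-1).  Per-allele consequence annotation is matched by allele string.
    """
    n_alts = len(record.alts)
    if n_alts < 1:
        raise VcfFormatError(f"{record.chrom}:{record.pos} has no ALT allele")
    dosage = np.zeros((n_alts, len(record.genotypes)), dtype=np.int8)
    for s, gt in enumerate(record.genotypes):
        called = [a for a in gt if a >= 0]
        if not called:
            dosage[:, s] = MISSING
            continue
        for a in called:
            if a > n_alts:
                raise VcfFormatError(
                    f"{record.chrom}:{record.pos}: genotype allele index {a} "
                    f"out of range for {n_alts} ALT allele(s)"
                )
            if a > 0:
                dosage[a - 1, s] += 1
    out = []
    for k, alt in enumerate(record.alts):
        out.append(
            CaseVariant(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alt=alt,
                consequences=parse_consequences(record.annotation, ann_spec, alt),
                dosages=dosage[k],
                depths=record.depths,
                qd=record.qd,
            )
        )
    return out


def _overlaps(record: RawRecord, regions: list[tuple[str, int, int]]) -> bool:
    start = record.pos - 1
    end = start + len(record.ref)
    return any(c == record.chrom and start < e and end > s for c, s, e in regions)


def read_case_vcf(
    path: str,
    regions: list[tuple[str, int, int]] | None = None,
    ann_spec: AnnotationSpec = AnnotationSpec(),
) -> CaseCohort:
    """Read a multi-sample VCF into a :class:`CaseCohort`.

    ``regions`` are 0-based half-open (chrom, start, end) intervals; when
    empty or None all records are returned.  Records are split per ALT allele;
    exact duplicates (same chrom:pos:ref:alt) after splitting are dropped with
    a warning.  Sample order follows the VCF header.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfFormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    if "##FORMAT=<ID=GT," not in vcf.raw_header:
        raise VcfFormatError(f"{path}: header declares no GT FORMAT field")
    samples = list(vcf.samples)

    use_regions = list(regions or [])
    contigs = set(vcf.seqnames)
    if contigs and use_regions:
        kept = []
        for reg in use_regions:
            if reg[0] not in contigs:
                logger.warning("region %s: contig unknown to VCF, skipped", reg)
            else:
                kept.append(reg)
        use_regions = kept
        if regions and not use_regions:
            vcf.close()
            return CaseCohort(samples=samples, variants=[])

    variants: list[CaseVariant] = []
    seen: set[str] = set()
    for v in vcf:
        dp = None
        try:
            raw_dp = v.format("DP")
        except KeyError:
            raw_dp = None
        if raw_dp is not None:
            dp = np.asarray(raw_dp).reshape(len(samples)).astype(np.int64)
            dp = np.where((dp < 0) | (dp > 2**31 - 2), MISSING, dp)
        qd = v.INFO.get("QD")
        rec = RawRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alts=list(v.ALT),
            genotypes=[tuple(gt[:-1]) for gt in v.genotypes],
            depths=dp,
            qd=float(qd) if qd is not None else None,
            annotation=v.INFO.get(ann_spec.field),
        )
        if use_regions and not _overlaps(rec, use_regions):
            continue
        if not rec.alts:
            continue
        for cv in split_multiallelic(rec, ann_spec):
            if cv.key in seen:
                logger.warning("duplicate record %s dropped", cv.key)
                continue
            seen.add(cv.key)
            variants.append(cv)
    vcf.close()
    return CaseCohort(samples=samples, variants=variants)


def write_case_vcf(
    cohort: CaseCohort, path: str, ann_field: str = "CSQ"
) -> None:
    """Write a cohort as an uncompressed multi-sample VCF v4.2.

    Each variant becomes one biallelic record; dosages map to unphased
    genotypes 0/0, 0/1, 1/1 and ./..  Consequence sets are emitted as a single
    ``Allele|Consequence`` annotation entry so that reading the file back
    reproduces the dosage matrix and consequence sets.
    """
    contigs = sorted({v.chrom for v in cohort.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n'
        )
        fh.write(
            f'##INFO=<ID={ann_field},Number=.,Type=String,'
            'Description="Consequence annotations. Format: Allele|Consequence">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for v in sorted(cohort.variants, key=lambda x: (x.chrom, x.pos, x.alt)):
            info = []
            if v.qd is not None:
                info.append(f"QD={v.qd:g}")
            if v.consequences:
                info.append(f"{ann_field}={v.alt}|{'&'.join(sorted(v.consequences))}")
            info_s = ";".join(info) or "."
            fmt = "GT:DP" if v.depths is not None else "GT"
            cols = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", info_s, fmt]
            for i in range(cohort.n_cases):
                g = gt_map[int(v.dosages[i])]
                if v.depths is not None:
                    d = int(v.depths[i])
                    g += ":" + (str(d) if d >= 0 else ".")
                cols.append(g)
            fh.write("\t".join(cols) + "\n")


def merge_cohorts(*cohorts: CaseCohort) -> CaseCohort:
    """Union samples and variants of several cohorts into one.

    Genotypes of samples absent from the cohort contributing a variant are
    filled as missing.  Sample identifiers must be disjoint across cohorts.
    """
    samples: list[str] = []
    for c in cohorts:
        clash = set(samples) & set(c.samples)
        if clash:
            raise VcfFormatError(f"sample identifiers shared across cohorts: {clash}")
        samples.extend(c.samples)
    n = len(samples)
    offsets = {}
    off = 0
    for c in cohorts:
        offsets[id(c)] = off
        off += c.n_cases

    merged: dict[str, CaseVariant] = {}
    for c in cohorts:
        off = offsets[id(c)]
        for v in c.variants:
            cur = merged.get(v.key)
            if cur is None:
                dos = np.full(n, MISSING, dtype=np.int8)
                dep = np.full(n, MISSING, dtype=np.int64) if v.depths is not None else None
                cur = replace(v, dosages=dos, depths=dep,
                              consequences=set(v.consequences))
                merged[v.key] = cur
            cur.dosages[off:off + c.n_cases] = v.dosages
            if v.depths is not None:
                if cur.depths is None:
                    cur.depths = np.full(n, MISSING, dtype=np.int64)
                cur.depths[off:off + c.n_cases] = v.depths
            cur.consequences |= v.consequences
    order = sorted(merged.values(), key=lambda x: (x.chrom, x.pos, x.alt))
    return CaseCohort(samples=samples, variants=order)


def filter_mean_depth(cohort: CaseCohort, min_mean_depth: float = 10) -> CaseCohort:
    """Drop variants with mean depth below ``min_mean_depth``.

    The mean is over samples with a depth value.  Sites where no sample has a
    depth value are retained with a warning (depth unassessable).
    """
    if min_mean_depth < 0:
        raise ValueError("min_mean_depth must be >= 0")
    kept = []
    for v in cohort.variants:
        md = v.mean_depth
        if md is None:
            logger.warning("variant %s has no depth values; retained", v.key)
            kept.append(v)
        elif md >= min_mean_depth:
            kept.append(v)
    return CaseCohort(samples=cohort.samples, variants=kept)


def filter_qd(
    cohort: CaseCohort, min_qd: float = 4, enabled: bool = True
) -> CaseCohort:
    """Retain variants with QD strictly greater than ``min_qd``.

    Variants lacking a QD value are retained with a warning.  When
    ``enabled`` is False the cohort is returned unchanged (the QD filter is
    an extra QC step applied to one cohort only).
    """
    if not enabled:
        return cohort
    kept = []
    for v in cohort.variants:
        if v.qd is None:
            logger.warning("variant %s has no QD value; retained", v.key)
            kept.append(v)
        elif v.qd > min_qd:
            kept.append(v)
    return CaseCohort(samples=cohort.samples, variants=kept)
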