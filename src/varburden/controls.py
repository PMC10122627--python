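"""Summary-statistic control sites (gnomAD-style AC/AN/nhomalt extracts).

The control cohort is represented only by per-site summary statistics: the
alternate allele count (AC), the number of called alleles (AN) and the number
of homozygous-alternate individuals (nhomalt).  True control carrier counts
are not available and are approximated downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .consequence import AnnotationSpec, parse_consequences
from .errors import VcfFormatError

logger = logging.getLogger(__name__)


@dataclass
class ControlSite:
    """One biallelic control site with summary statistics."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ac: int
    an: int
    nhomalt: int = 0
    consequences: set[str] = field(default_factory=set)
    filter_pass: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.ac <= self.an:
            raise ValueError(
                f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}: "
                f"AC={self.ac} outside [0, AN={self.an}]"
            )
        if 2 * self.nhomalt > self.ac:
            raise ValueError(
                f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}: "
                f"2*nhomalt={2 * self.nhomalt} exceeds AC={self.ac}"
            )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )


def _site_or_none(**kw) -> ControlSite | None:
    try:
        return ControlSite(**kw)
    except ValueError as exc:
        logger.error("control record rejected: %s", exc)
        return None


def _load_tsv(path: str, ann_spec: AnnotationSpec) -> list[ControlSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "ac", "an"}
    missing = required - set(df.columns)
    if missing:
        raise VcfFormatError(f"control TSV lacks columns: {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        if pd.isna(getattr(row, "an", None)):
            logger.error("control record at %s:%s rejected: missing AN",
                         row.chrom, row.pos)
            continue
        cons_raw = getattr(row, "consequence", None)
        cons = (
            set(str(cons_raw).split("&"))
            if cons_raw is not None and not pd.isna(cons_raw) and str(cons_raw)
            else set()
        )
        filt = getattr(row, "filter", "PASS")
        site = _site_or_none(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            ac=int(row.ac),
            an=int(row.an),
            nhomalt=int(getattr(row, "nhomalt", 0) or 0),
            consequences=cons,
            filter_pass=(str(filt) in ("PASS", ".", "nan")),
        )
        if site is not None:
            sites.append(site)
    return sites


def _per_alt(value, k: int, n_alts: int, default=0) -> int:
    """Pick the k-th element of a per-ALT INFO value (scalar when biallelic)."""
    if value is None:
        return default
    if isinstance(value, (tuple, list)):
        return int(value[k]) if k < len(value) else default
    if n_alts == 1:
        return int(value)
    return default


def _load_sites_vcf(path: str, ann_spec: AnnotationSpec) -> list[ControlSite]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfFormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    sites = []
    for v in vcf:
        an = v.INFO.get("AN")
        if an is None:
            logger.error("control record %s:%s rejected: missing AN", v.CHROM, v.POS)
            continue
        ac = v.INFO.get("AC")
        nhom = v.INFO.get("nhomalt")
        ann = v.INFO.get(ann_spec.field)
        n_alts = len(v.ALT)
        for k, alt in enumerate(v.ALT):
            site = _site_or_none(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                ac=_per_alt(ac, k, n_alts),
                an=int(an),
                nhomalt=_per_alt(nhom, k, n_alts),
                consequences=parse_consequences(ann, ann_spec, alt),
                filter_pass=v.FILTER is None,  # cyvcf2: None == PASS
            )
            if site is not None:
                sites.append(site)
    vcf.close()
    return sites


def load_control_sites(
    path: str,
    fmt: str | None = None,
    pass_only: bool = True,
    ann_spec: AnnotationSpec = AnnotationSpec(),
) -> list[ControlSite]:
    """Load control summary sites from a sites-only VCF or a TSV.

    The TSV carries columns chrom, pos, ref, alt, ac, an and optionally
    nhomalt, consequence (``&``-joined terms) and filter.  Multiallelic VCF
    records are split into per-allele sites with per-allele AC/nhomalt.
    Records violating AC <= AN or 2*nhomalt <= AC, or lacking AN, are rejected
    with an error logged.  Non-PASS sites are dropped when ``pass_only``.
    """
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    sites = (
        _load_sites_vcf(path, ann_spec) if fmt == "vcf" else _load_tsv(path, ann_spec)
    )
    if pass_only:
        sites = [s for s in sites if s.filter_pass]
    return sites


def write_control_tsv(sites: list[ControlSite], path: str) -> None:
    """Write control sites as the package's TSV interchange format."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tac\tan\tnhomalt\tconsequence\tfilter\n")
        for s in sites:
            cons = "&".join(sorted(s.consequences))
            filt = "PASS" if s.filter_pass else "FAIL"
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.ac}\t{s.an}\t"
                f"{s.nhomalt}\t{cons}\t{filt}\n"
            )
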