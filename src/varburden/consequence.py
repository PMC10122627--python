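"""Parsing of VEP-style consequence annotations from a VCF INFO field.

The annotation field (``CSQ`` by default) holds one entry per transcript,
entries comma-separated, sub-fields separated by ``|``.  Each entry names the
alternate allele it describes and one or more ``&``-joined consequence terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

MISSENSE = "missense_variant"


@dataclass(frozen=True)
class AnnotationSpec:
    """Layout of the consequence annotation INFO field.

    ``allele_index`` / ``consequence_index`` / ``canonical_index`` are the
    positions of the allele, consequence and CANONICAL sub-fields within each
    ``separator``-delimited transcript entry.  ``transcript_policy`` is
    ``"any"`` (a term counts if any transcript carries it) or ``"canonical"``
    (only entries flagged CANONICAL contribute).
    """

    field: str = "CSQ"
    separator: str = "|"
    allele_index: int | None = 0
    consequence_index: int = 1
    canonical_index: int | None = None
    transcript_policy: str = "any"

    def __post_init__(self) -> None:
        if self.transcript_policy not in ("any", "canonical"):
            raise ValueError(
                f"transcript_policy must be 'any' or 'canonical', "
                f"got {self.transcript_policy!r}"
            )
        if self.transcript_policy == "canonical" and self.canonical_index is None:
            raise ValueError("canonical policy requires canonical_index")


def parse_consequences(
    raw: str | None,
    spec: AnnotationSpec = AnnotationSpec(),
    allele: str | None = None,
) -> set[str]:
    """Return the set of consequence terms attached to ``allele``.

    Terms are the union over all transcript entries matching the allele
    (all entries when ``allele`` is None or the spec has no allele sub-field);
    ``&``-joined terms are split into atoms.  An absent or empty annotation
    yields the empty set; malformed entries are skipped with a warning.
    """
    if not raw:
        return set()
    terms: set[str] = set()
    for entry in str(raw).split(","):
        parts = entry.split(spec.separator)
        if len(parts) <= spec.consequence_index:
            logger.warning("malformed annotation entry skipped: %r", entry)
            continue
        if (
            allele is not None
            and spec.allele_index is not None
            and len(parts) > spec.allele_index
            and parts[spec.allele_index] != allele
        ):
            continue
        if spec.transcript_policy == "canonical":
            if len(parts) <= spec.canonical_index:
                logger.warning("annotation entry lacks CANONICAL field: %r", entry)
                continue
            if parts[spec.canonical_index] not in ("YES", "1"):
                continue
        terms.update(t for t in parts[spec.consequence_index].split("&") if t)
    return terms
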