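"""Exception types shared across the package."""


class VarBurdenError(Exception):
    """Base class for all package errors."""


class VcfFormatError(VarBurdenError):
    """A VCF could not be parsed or lacks a required field (e.g. GT)."""


class GeneModelError(VarBurdenError):
    """A gene model file is malformed or a gene has no exons."""


class SnpFileError(VarBurdenError):
    """The per-gene variant group ("SNP") file is malformed."""


class ConsistencyError(VarBurdenError):
    """Counts imply an impossible contingency table (negative cell)."""


class UntestableGeneError(VarBurdenError):
    """A contingency table has a zero case margin and cannot be tested."""
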