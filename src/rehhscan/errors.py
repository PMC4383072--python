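"""Exception taxonomy shared by all modules."""


class RehhscanError(Exception):
    """Base class for all package errors."""


class ParseError(RehhscanError):
    """Malformed input file (names the offending line where possible)."""


class DimensionError(RehhscanError):
    """Inconsistent dimensions between genotype/haplotype data and marker map."""


class PhaseError(RehhscanError):
    """Unphased genotype encountered where phased data are required."""


class UndefinedStatisticError(RehhscanError):
    """Statistic undefined for the given input (e.g. monomorphic marker, <2 carriers)."""


class DomainError(RehhscanError):
    """Value outside its documented domain."""


class ConfigError(RehhscanError):
    """Invalid configuration; message lists the offending fields."""


class PedigreeError(RehhscanError):
    """Inconsistent pedigree (duplicate ids, self-sire, ...)."""


class MapMismatchError(RehhscanError):
    """Two datasets that must share a marker map do not."""


class NamespaceError(RehhscanError):
    """Chromosome naming of two inputs does not intersect."""


class MissingMarkerError(RehhscanError):
    """No marker close enough to the requested genetic distance."""


class DegenerateBinError(RehhscanError):
    """All rEHH values collapse into one zero-variance bin."""


class SweepFailureError(RehhscanError):
    """Selected allele never reached its target frequency window within the retry budget."""
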