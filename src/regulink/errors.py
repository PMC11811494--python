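"""Typed exceptions shared across the package."""


class RegulinkError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RegulinkError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line_number: int | None = None):
        self.path = path
        self.line_number = line_number
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line_number is not None:
            prefix += f"line {line_number}: "
        super().__init__(prefix + message)


class DuplicateIdError(RegulinkError):
    """An identifier that must be unique occurred more than once."""


class ChromosomeMismatchError(RegulinkError):
    """Peak and annotation chromosome names share no common name.

    Chromosome naming is never normalised (no chr-prefix stripping); a
    disjoint name set almost always means mismatched conventions.
    """

    def __init__(self, peak_chroms, region_chroms):
        self.peak_chroms = sorted(peak_chroms)
        self.region_chroms = sorted(region_chroms)
        super().__init__(
            "no peak chromosome matches any annotation chromosome; "
            f"peaks use {self.peak_chroms}, regions use {self.region_chroms}"
        )


class NoAnnotatedGenesError(RegulinkError):
    """The gene selection contains no gene with a usable annotation."""


class CycleError(RegulinkError):
    """The ontology graph contains a cycle."""


class UnknownGeneError(RegulinkError):
    """A gene identifier could not be resolved against the annotation."""
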