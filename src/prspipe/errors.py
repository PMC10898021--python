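"""Exception hierarchy for the pipeline."""


class PrsPipeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PrsPipeError):
    """A file on disk does not conform to its declared format."""


class ConfigurationError(PrsPipeError):
    """Invalid or incomplete user configuration."""


class EmptyIntersectionError(PrsPipeError):
    """No SNPs shared between genotypes and summary statistics."""


class DegenerateDataError(PrsPipeError):
    """Input has no usable variation (constant scores, zero variance, ...)."""


class IncompleteLDTableError(PrsPipeError):
    """The external LD table lacks a required pairwise r² entry."""
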