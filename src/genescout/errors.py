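"""Exception hierarchy shared across the pipeline stages."""


class GenescoutError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(GenescoutError):
    """Bad or incomplete configuration (missing external tool, invalid parameter)."""


class InputParseError(GenescoutError):
    """Malformed input file (FASTA/GFF3/BLAST tabular/TSV)."""


class NoUsableQueriesError(GenescoutError):
    """Every query sequence was removed by quality control."""


class StageError(GenescoutError):
    """A pipeline stage received inputs that violate its preconditions."""
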