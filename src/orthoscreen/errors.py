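"""Exception hierarchy shared across the screening pipeline."""


class OrthoscreenError(Exception):
    """Base class for all package errors."""


class FormatError(OrthoscreenError):
    """A file could not be parsed; message names the file and record."""


class CoordinateError(OrthoscreenError):
    """CDS coordinates violate the 1-based inclusive convention or fall
    outside the contig; message names the gene."""


class AlphabetError(OrthoscreenError):
    """A sequence contains characters outside its declared alphabet."""


class InputError(OrthoscreenError):
    """Operation preconditions violated (empty sequence, reference mismatch,
    EXCLUDED call passed where a classified call is required, ...)."""


class ConfigError(OrthoscreenError):
    """Invalid configuration value or an infeasible simulation plan."""
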