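"""Exception hierarchy.

Exit-code convention for the CLI: 0 ok, 1 data error, 2 configuration error.
"""


class BulksegError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(BulksegError):
    """Invalid configuration: bad thresholds, loci outside the genome, unknown samples."""

    exit_code = 2


class DataError(BulksegError):
    """Invalid or insufficient input data."""

    exit_code = 1


class BulkShortfallError(DataError):
    """Fewer qualifying plants than a bulk specification requires."""
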