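"""Exception hierarchy with stable CLI exit codes.

Every error raised by the library derives from :class:`MachkitError`; the CLI
maps the ``exit_code`` attribute straight to the process exit status so that
shell pipelines can distinguish QC failures from format or I/O problems.
"""


class MachkitError(Exception):
    """Base class for all machkit errors."""

    exit_code = 1


class FormatError(MachkitError):
    """A file does not conform to its expected text format."""

    exit_code = 4


class DimensionError(MachkitError):
    """Row/column counts disagree with the companion file or expectation."""

    exit_code = 4


class QcError(MachkitError):
    """A structural quality-control check failed."""

    exit_code = 3


class HarmonizationError(MachkitError):
    """Variant metadata (names, order, alleles) disagrees between inputs."""

    exit_code = 5


class IdentityError(MachkitError):
    """Duplicate sample identities where disjoint sets are required."""

    exit_code = 5


class EmptyIntersectionError(MachkitError):
    """No variant is shared by all datasets; merging zero SNPs is refused."""

    exit_code = 5


class ArgumentError(MachkitError):
    """Invalid argument values passed to a library operation."""

    exit_code = 2


class FileIOError(MachkitError):
    """An input or output path could not be read or written."""

    exit_code = 6
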