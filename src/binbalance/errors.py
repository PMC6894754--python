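"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`BinBalanceError`, so callers can catch one type at pipeline level
while tests assert on the specific subclass.
"""


class BinBalanceError(Exception):
    """Base class for all errors raised by binbalance."""


class InvalidArgumentError(BinBalanceError, ValueError):
    """A parameter violates a documented precondition."""


class UnknownReferenceError(BinBalanceError, KeyError):
    """A chromosome name is absent from the reference dictionary."""


class CoordinateError(BinBalanceError, ValueError):
    """A position or bin index lies outside its chromosome."""


class MalformedSAMError(BinBalanceError, ValueError):
    """A SAM record line cannot be interpreted (too few fields, bad POS...)."""


class ContainerFormatError(BinBalanceError, ValueError):
    """A container file does not start with the expected magic/version."""


class ContainerCorruptionError(BinBalanceError, ValueError):
    """A container file or compressed payload is truncated or undecodable."""


class BinsInfoParseError(BinBalanceError, ValueError):
    """A bins-info sidecar line is malformed."""


class MapperInvocationError(BinBalanceError, RuntimeError):
    """An external mapper command failed."""


class RegionCommandError(BinBalanceError, RuntimeError):
    """An external per-region command (variant discovery hook) failed."""


class ConsistencyError(BinBalanceError, RuntimeError):
    """Cross-file bookkeeping disagrees (e.g. a container bin missing from a regions map)."""


class FastqParseError(BinBalanceError, ValueError):
    """A FASTQ stream violates the 4-line record structure."""


class PairingError(BinBalanceError, ValueError):
    """Mate-1 and mate-2 FASTQ streams diverge (unequal record counts)."""


class VcfMergeError(BinBalanceError, ValueError):
    """Per-region VCF files cannot be combined (incompatible headers)."""


class ConfigError(BinBalanceError, ValueError):
    """Pipeline configuration is invalid or incomplete."""


class InputError(BinBalanceError, FileNotFoundError):
    """A required input file or directory is missing."""
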