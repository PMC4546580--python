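"""Exception hierarchy shared across the package."""


class PolysegError(Exception):
    """Base class for all package-specific errors."""


class InvalidGenotypeError(PolysegError, ValueError):
    """A genotype does not satisfy the structural requirements of its mode."""


class MappingError(PolysegError, KeyError):
    """An allele has no image under the supplied band-size alias map."""


class ParseError(PolysegError, ValueError):
    """A marker table file is malformed (ragged rows, bad header...)."""


class ValidationError(PolysegError, ValueError):
    """Structured input violates a declared contract (duplicate IDs,
    unknown pattern classes, mismatched marker panels...)."""


class DegenerateTestError(PolysegError, ValueError):
    """A goodness-of-fit test has fewer than two informative classes."""


class AmbiguousPartitionError(PolysegError, ValueError):
    """Two-locus decomposition cannot choose between allele pairings."""


class DecompositionFailedError(PolysegError, ValueError):
    """No allele pairing explains the observed joint phenotypes."""


class ConfigError(PolysegError, ValueError):
    """An analysis run configuration is incomplete or inconsistent."""
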