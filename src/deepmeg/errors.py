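"""Exception hierarchy shared across the pipeline."""


class DeepMegError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(DeepMegError, ValueError):
    """A configuration value is out of its admissible range."""


class DegenerateFitError(DeepMegError, ValueError):
    """Geometry fit is underdetermined (e.g. coplanar scalp points)."""


class EmptySourceSpaceError(DeepMegError, ValueError):
    """A source-space construction produced no sources."""


class AssemblyError(DeepMegError, ValueError):
    """Gain-matrix assembly received inconsistent or empty inputs."""


class DomainError(DeepMegError, ValueError):
    """A physical evaluation was requested outside its domain of validity."""


class RegularizationError(DeepMegError, RuntimeError):
    """The inverse system could not be stabilised at the requested tolerance."""


class IncompleteDesignError(DeepMegError, ValueError):
    """A repeated-measures table is missing factorial cells."""


class EmptyConditionError(DeepMegError, ValueError):
    """No trials survived selection for a condition."""
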