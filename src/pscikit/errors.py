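"""Exception types shared across the pipeline."""


class PscikitError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PscikitError, ValueError):
    """An invalid generator or run configuration."""


class MappingError(PscikitError, KeyError):
    """A raw value (education code, test name) has no harmonization rule."""


class SeparationError(PscikitError, RuntimeError):
    """A logistic fit diverged: the data are (quasi-)completely separated."""


class ConvergenceError(PscikitError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""
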