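"""Exception hierarchy shared across the pipeline."""


class FmenkitError(Exception):
    """Base class for all fmenkit errors."""


class ConfigError(FmenkitError):
    """Invalid configuration (bad dimensions, missing paths, ...)."""


class InputError(FmenkitError):
    """Malformed input data (duplicate ids, negative counts, ...)."""


class EmptyResultError(FmenkitError):
    """A filtering step removed everything."""


class EmptyNetworkError(FmenkitError):
    """A correlation cutoff left no edges."""


class NoTransitionError(FmenkitError):
    """The RMT scan found no usable Poisson/GOE transition."""
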