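"""Exception types shared across the pipeline."""


class IsowebError(Exception):
    """Base class for all package errors."""


class ConfigError(IsowebError):
    """A configuration value violates an invariant; the message names it."""


class InputError(IsowebError):
    """An input table failed validation; the message names row and field."""


class GeometryError(IsowebError):
    """A geometric operation received degenerate input (e.g. <3 sources)."""
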