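"""Exception types shared across the pipeline."""


class PeriradError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PeriradError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class EmptyMaskError(PeriradError, ValueError):
    """A mask is empty where a nonempty region is required."""


class GridMismatchError(PeriradError, ValueError):
    """Paired volume/mask grids (shape, spacing, origin) do not match."""
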