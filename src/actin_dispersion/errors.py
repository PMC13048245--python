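"""Exception hierarchy.

``DataError`` subclasses mark inputs on which the metric is undefined
(no detectable fibers, no nucleus to anchor distances); batch drivers
catch them per image instead of aborting.
"""


class ActinDispersionError(Exception):
    """Base class for all package errors."""


class ParameterError(ActinDispersionError, ValueError):
    """An invalid parameter value (sigma <= 0, reduction ratio < 1, ...)."""


class FormatError(ActinDispersionError, ValueError):
    """An image whose layout the pipeline does not support."""


class ConfigurationError(ActinDispersionError, ValueError):
    """A channel role or config entry that cannot be resolved."""


class DataError(ActinDispersionError, ValueError):
    """Input content on which the requested quantity is undefined."""


class NoEdgesError(DataError):
    """No stress-fiber edges survive detection and length filtering."""


class NoNucleiError(DataError):
    """No blue (nuclear) region detected; distance features are undefined."""


class GenerationError(ActinDispersionError, RuntimeError):
    """Synthetic fixture could not be realized (overcrowded placement)."""
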