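"""Exception hierarchy shared across the package."""


class FdrvalError(Exception):
    """Base class for all package errors."""


class MapFormatError(FdrvalError):
    """Malformed or unwritable MRC file / header."""


class MapDataError(FdrvalError):
    """Grid data violates an invariant (NaN/Inf, bad geometry)."""


class ConfigurationError(FdrvalError):
    """A requested configuration cannot be satisfied (e.g. noise cubes
    do not fit between the box face and the guard sphere)."""


class DegenerateNoiseError(FdrvalError):
    """Background estimate has zero spread — typically a masked map."""


class ModelError(FdrvalError):
    """Unparseable or empty atomic model."""
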