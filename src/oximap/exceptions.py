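"""Exception types shared across the package."""


class OximapError(Exception):
    """Base class for package errors."""


class GeometryError(OximapError, ValueError):
    """A vessel or pixel set falls outside the image bounds."""


class FormatError(OximapError, ValueError):
    """A cube or sidecar file is malformed or inconsistent."""


class ConfigurationError(OximapError, ValueError):
    """Required configuration or metadata is missing or unusable."""


class DegeneracyError(OximapError, ValueError):
    """A fit problem is rank-deficient or otherwise unsolvable."""
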