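"""Exception hierarchy shared across the package."""


class MagforgeError(Exception):
    """Base class for all package errors."""


class BundleLoadError(MagforgeError):
    """A bundle file is missing or unparseable."""


class BundleValidationError(MagforgeError):
    """A loaded bundle violates a schema invariant."""


class DesignError(MagforgeError):
    """A synthetic community design is outside the supported regime."""


class ConfigurationError(MagforgeError):
    """A rule set or run configuration is invalid."""
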