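"""Exception types shared across the package."""


class ScarstError(Exception):
    """Base class for package-specific errors."""


class FormatError(ScarstError, ValueError):
    """A file does not conform to its declared dialect (names file/line where known)."""


class EmptyRegionError(ScarstError, ValueError):
    """An operation requires a non-empty spot set (scar region, interface side, layer)."""


class EmptyGeneSetError(ScarstError, ValueError):
    """A gene set has no member present in the expression matrix."""


class ConfigurationError(ScarstError, ValueError):
    """A run configuration or generator configuration is inconsistent."""
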