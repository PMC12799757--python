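"""Exception hierarchy.

Everything raised on purpose by the package derives from :class:`HemaspecError`
so callers can catch pipeline failures without masking programming errors.
"""


class HemaspecError(Exception):
    """Base class for all hemaspec-specific errors."""


class CalibrationError(HemaspecError):
    """White/dark reference is unusable (white <= dark in some band)."""


class MaskError(HemaspecError):
    """ROI mask is empty or does not match the cube's spatial shape."""


class EnviFormatError(HemaspecError):
    """ENVI header is missing a field or uses an unsupported dialect."""


class DatasetSchemaError(HemaspecError):
    """Dataset CSV violates the paired hematoma/skin row schema."""


class DegenerateReferenceError(HemaspecError):
    """Skin reference spectrum is too close to zero for division."""


class ConfigError(HemaspecError):
    """A run/generator configuration field is invalid or unknown."""
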