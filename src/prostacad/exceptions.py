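"""Exception hierarchy shared across the pipeline.

Each class maps to a distinct CLI exit code (see :mod:`prostacad.cli`).
"""


class ProstacadError(Exception):
    """Base class for all package errors."""


class ImageIOError(ProstacadError):
    """A volume or mask could not be read or written."""


class GeometryError(ProstacadError):
    """Channels of a case bundle disagree on grid shape, spacing, or origin."""


class SchemaError(ProstacadError):
    """A serialized model/config file is malformed, unsupported, or tampered."""


class DegenerateDataError(ProstacadError):
    """A statistical operation received data it is undefined on
    (single-class labels, empty ROI after re-segmentation, zero marginal...)."""
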