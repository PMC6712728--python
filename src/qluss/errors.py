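"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`QlussError` so CLI
wrappers can map failures to a single machine-parseable category line.
"""


class QlussError(Exception):
    """Base class for all package errors."""

    category = "error"


class InputError(QlussError):
    """Unreadable, empty or malformed input file."""

    category = "input-error"


class UnsupportedFormatError(QlussError):
    """Input decodes but is not a supported still-frame format."""

    category = "unsupported-format"


class DegenerateROIError(QlussError):
    """Pleural-line placement leaves too few analyzable rows."""

    category = "degenerate-roi"


class DegenerateClusteringError(QlussError):
    """Binarization is undefined (single-valued region of interest)."""

    category = "degenerate-clustering"


class ConfigurationError(QlussError):
    """A configuration value is out of its documented domain."""

    category = "configuration-error"


class IncompleteExamError(QlussError):
    """A patient exam is missing one or more of the standard regions."""

    category = "incomplete-exam"


class InconsistentAnnotationError(QlussError):
    """A clinician annotation violates the pattern/field consistency rules."""

    category = "inconsistent-annotation"


class AnalysisError(QlussError):
    """A statistical routine was called on data outside its domain."""

    category = "analysis-error"
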