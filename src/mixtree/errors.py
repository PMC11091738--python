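"""Exception hierarchy.

Every error raised by the library derives from :class:`MixtreeError`, so the
CLI can map library failures to exit code 1 while genuine usage errors
(unknown flags, missing arguments) surface as exit code 2 via click.
"""


class MixtreeError(Exception):
    """Base class for all mixtree errors."""


class ConfigurationError(MixtreeError):
    """Invalid user configuration (e.g. class column not in the header)."""


class FormatError(MixtreeError):
    """Malformed input file (CSV structure, JSON tree document)."""


class VersionError(FormatError):
    """Tree document carries an unsupported format version."""


class DataError(MixtreeError):
    """A cell value violates its attribute's resolved type."""


class StructuralError(MixtreeError):
    """A test, path, or tree references something that does not exist
    or violates a structural invariant."""


class ResolutionError(StructuralError):
    """A name in a test expression does not resolve to a dataset attribute."""


class ExpressionParseError(MixtreeError):
    """A test expression does not match the canonical grammar."""


class NotApplicableError(MixtreeError):
    """The requested operation has no legal result on this input
    (e.g. TSP search with fewer than two continuous attributes)."""


class DegenerateSplitError(MixtreeError):
    """A split with an empty side; its split information would be zero."""


class InputError(MixtreeError):
    """Empty or degenerate input where data is required."""
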