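"""Exception hierarchy for the recognition pipeline.

Every failure the pipeline can diagnose derives from :class:`PhylopixError`
so the orchestrator can convert it into a failed-status result instead of a
traceback. Subclasses distinguish bad user input from images the recognizer
cannot interpret.
"""


class PhylopixError(Exception):
    """Base class for all recognition-pipeline failures."""


class InputFormatError(PhylopixError):
    """The input file is missing, unreadable, or not PNG/JPEG/GIF."""


class ParameterError(PhylopixError, ValueError):
    """A caller-supplied parameter is outside its documented domain."""


class RecognitionError(PhylopixError):
    """The image content cannot be interpreted as a rectangular phylogram."""


class NetworkError(RecognitionError):
    """The line skeleton contains a cycle: the drawing is a network, not a tree."""


class MalformedJunctionError(RecognitionError):
    """A vertical connector joins fewer than two child branches."""


class ConfigurationError(PhylopixError):
    """The pipeline configuration is unusable (e.g. OCR engine not installed)."""
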