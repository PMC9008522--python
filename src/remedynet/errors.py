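"""Exception hierarchy shared across the pipeline."""


class RemedyNetError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(RemedyNetError, ValueError):
    """A numeric or structural parameter is outside its documented range."""


class ParseError(RemedyNetError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(RemedyNetError, ValueError):
    """A record is syntactically valid but lacks a required field."""


class ConflictError(RemedyNetError, ValueError):
    """The same surface form was registered with conflicting labels."""


class InvalidAnnotationError(RemedyNetError, ValueError):
    """Annotations violate a structural contract (e.g. overlapping spans)."""


class CoverageError(RemedyNetError, KeyError):
    """A mapping is not total on the surfaces it is applied to."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "canonical map does not cover %d surface(s): %s"
            % (len(self.missing), ", ".join(self.missing[:10]))
        )


class UndefinedPMIError(RemedyNetError, ValueError):
    """PMI is undefined because a marginal probability is zero."""


class EmptyCorpusError(RemedyNetError, ValueError):
    """An operation that needs at least one sentence/edge received none."""


class DependencyError(RemedyNetError, RuntimeError):
    """A pipeline stage was invoked before its upstream stage."""
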