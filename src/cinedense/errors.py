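"""Exception hierarchy shared by all cinedense modules."""


class DenseError(Exception):
    """Base class for all cinedense errors."""


class SchemaError(DenseError):
    """A file is missing a required key/dataset, or has an unknown layout."""


class ValidationError(DenseError):
    """An in-memory object violates one of its documented invariants."""


class GeometryError(ValidationError):
    """A contour or mesh violates a geometric precondition."""


class InsufficientDataError(ValidationError):
    """Too few samples/frames/slices for the requested computation."""


class StageError(DenseError):
    """Failure inside a named pipeline stage; wraps the original error."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
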