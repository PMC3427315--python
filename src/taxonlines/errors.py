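"""Exception hierarchy shared across the pipeline stages."""


class TaxonlinesError(Exception):
    """Base class for all package errors."""


class AlignmentError(TaxonlinesError):
    """Malformed or inconsistent sequence alignment input."""


class MetadataError(TaxonlinesError):
    """Sample metadata missing, duplicated or unresolvable."""


class SchemaError(TaxonlinesError):
    """Morphology table header does not declare a valid schema."""


class UndefinedDistanceError(TaxonlinesError):
    """A pairwise distance has zero comparable sites."""


class StageError(TaxonlinesError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
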