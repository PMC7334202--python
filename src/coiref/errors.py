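"""Exception hierarchy shared across the package."""


class CoirefError(Exception):
    """Base class for all coiref errors."""


class TaxdumpParseError(CoirefError):
    """Malformed names.dmp / nodes.dmp input."""


class TaxonomyError(CoirefError):
    """Invalid taxonomy operation (unknown TaxID, bad mint, broken tree)."""


class GenBankParseError(CoirefError):
    """Malformed GenBank flatfile input (e.g. truncated final entry)."""


class BoldFormatError(CoirefError):
    """BOLD-style TSV missing a mandatory column."""


class ExportError(CoirefError):
    """Database not exportable (unnormalized record, duplicate accession)."""


class StageError(CoirefError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
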