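"""Exception hierarchy for mirmint.

All pipeline errors derive from :class:`MirmintError` so callers can catch
one base class; parameter problems additionally derive from ``ValueError``.
"""


class MirmintError(Exception):
    """Base class for all mirmint errors."""


class MatrixFormatError(MirmintError):
    """An expression matrix file is malformed (duplicate/missing IDs, non-numeric cells)."""


class DesignError(MirmintError):
    """The sample design is inconsistent with a matrix or with itself."""


class ParameterError(MirmintError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class ConfigError(MirmintError, ValueError):
    """A run configuration is invalid."""


class DegenerateInputError(MirmintError):
    """The input is too small or too uniform for the operation to be defined."""


class PairingError(MirmintError):
    """Gene and miRNA matrices do not share the sample set required for correlation."""


class NamespaceError(MirmintError):
    """An identifier does not belong to the expected namespace (unknown miR or gene)."""


class IncompleteSummaryError(MirmintError):
    """A pipeline summary was requested while some stages are missing."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing pipeline stages: {', '.join(self.missing)}")
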