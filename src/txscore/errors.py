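"""Exception hierarchy shared across the package."""


class TxScoreError(Exception):
    """Base class for all txscore errors."""


class FormatError(TxScoreError):
    """A file did not conform to the expected on-disk format."""


class DesignError(TxScoreError):
    """The sample design is inconsistent or insufficient for an analysis."""


class ConsistencyError(TxScoreError):
    """Two inputs that must share a universe (genes, samples) disagree."""
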