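"""Exception hierarchy for xtalselect."""


class XtalSelectError(Exception):
    """Base class for all xtalselect errors."""


class SequenceError(XtalSelectError):
    """Invalid amino-acid sequence (illegal characters, empty, unscoreable)."""


class FastaFormatError(XtalSelectError):
    """Malformed FASTA input (empty file, empty body, duplicate ids)."""


class ModelError(XtalSelectError):
    """Model construction or use failed (insufficient data, bad grid, ...)."""


class EvaluationError(XtalSelectError):
    """Evaluation statistic undefined for the given input (e.g. one class)."""
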