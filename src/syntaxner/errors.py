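class FormatError(ValueError):
    """Malformed input file (bad column, tag grammar, ID sequence...)."""


class ValidationError(ValueError):
    """Well-formed input violating a documented precondition."""


class AlignmentError(ValueError):
    """Subword-to-word alignment failure."""
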