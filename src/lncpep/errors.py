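"""Exception hierarchy for the lncpep pipeline."""


class LncpepError(Exception):
    """Base class for all pipeline errors."""


class InputError(LncpepError):
    """Malformed biological input (sequence, record, identifier)."""


class ParameterError(LncpepError):
    """A parameter value outside its valid domain."""


class FormatError(LncpepError):
    """A file that does not conform to its declared format."""


class IntegrityError(LncpepError):
    """Packaged reference data failing its own invariants."""
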