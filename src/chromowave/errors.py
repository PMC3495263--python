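"""Exception hierarchy shared across the pipeline."""


class ChromowaveError(Exception):
    """Base class for all errors raised by this package."""


class InputError(ChromowaveError, ValueError):
    """A caller supplied arguments that violate a precondition."""


class FormatError(ChromowaveError, ValueError):
    """An on-disk table is malformed (duplicate keys, non-numeric cells...)."""


class ComputationError(ChromowaveError, RuntimeError):
    """The computation is undefined on this input (zero variance, empty sets...)."""
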