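"""Exception hierarchy shared by all pipeline stages."""


class TrendsigError(Exception):
    """Base class for all package errors."""


class InputError(TrendsigError):
    """A required input file is missing, unreadable or malformed."""


class ValidationError(TrendsigError):
    """Inputs parsed fine but violate a contract (bad labels, empty class, ...)."""
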