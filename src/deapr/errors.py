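"""Exception hierarchy shared by all deapr modules."""


class DeaprError(Exception):
    """Base class for all deapr-specific failures."""


class ValidationError(DeaprError, ValueError):
    """Input violates a documented invariant (negative FPKM, duplicate id, ...)."""


class ParseError(DeaprError, ValueError):
    """A cell in a tabular input could not be interpreted."""


class SchemaError(DeaprError, ValueError):
    """A tabular input is missing a required column or has the wrong shape."""
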