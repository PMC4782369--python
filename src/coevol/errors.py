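"""Exception hierarchy for the coevolution toolkit.

All library errors derive from :class:`CoevolError` so callers (and the CLI)
can distinguish domain failures from programming errors.
"""


class CoevolError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CoevolError, ValueError):
    """A file does not conform to its declared format."""


class InputError(CoevolError, ValueError):
    """Arguments or input contents violate a precondition."""


class ResidueLookupError(CoevolError, KeyError):
    """A residue label or record id was not found."""
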