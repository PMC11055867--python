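"""Exception types shared across the pipeline.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`EmptyResultError` -> 3.
"""


class TriwiError(Exception):
    """Base class for all package errors."""


class InputError(TriwiError):
    """Invalid or missing input (malformed table, bad parameter, absent file)."""


class EmptyResultError(TriwiError):
    """A stage produced an empty result the pipeline cannot proceed from."""
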