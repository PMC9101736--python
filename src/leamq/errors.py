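"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`SchemaError` -> 2,
:class:`ConfigError` -> 3, anything else -> 1.
"""


class LEAMQError(Exception):
    """Base class for package errors."""


class SchemaError(LEAMQError):
    """Input table violates the expected schema (missing columns,
    duplicate ids, non-numeric cells, unknown item ids).

    Carries the full list of row/column diagnostics so a caller sees every
    problem in one pass.
    """

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class ValidationError(LEAMQError):
    """A value is structurally valid but outside its allowed domain
    (e.g. an answer code outside the item's allowed codes, or a highest
    weight below the lowest weight)."""


class ConfigError(LEAMQError):
    """Scoring key / reference / pipeline configuration is inconsistent."""
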