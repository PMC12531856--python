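class ConfigurationError(ValueError):
    """Invalid module/model configuration (channel arithmetic, bad enum, ...)."""


class InputError(ValueError):
    """Invalid runtime input (non-finite values, wrong size, malformed labels)."""


class ParseError(InputError):
    """Malformed text input; carries the offending line number when known."""

    def __init__(self, message, line=None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line
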