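"""Exception taxonomy shared across the package."""


class InputError(ValueError):
    """Invalid runtime input (bad array values, mismatched lengths, ...)."""


class ConfigurationError(ValueError):
    """Invalid or inconsistent configuration (shapes, counts, ranges)."""


class DataError(ValueError):
    """A dataset record violates its contract (e.g. empty region mask)."""


class LeakageError(RuntimeError):
    """A case id appears on both the train and the evaluation side."""
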