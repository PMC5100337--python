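"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration object violates one of its invariants."""


class DataError(ValueError):
    """An input file or table is malformed or inconsistent."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""
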