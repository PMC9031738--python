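"""Exception hierarchy mapped to CLI exit codes (config=2, data=3, stage=4)."""


class TilepurifyError(Exception):
    exit_code = 1


class ConfigError(TilepurifyError):
    """Invalid configuration value or file."""

    exit_code = 2


class DataError(TilepurifyError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class StageError(TilepurifyError):
    """A pipeline stage failed; earlier stages remain resumable."""

    exit_code = 4
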