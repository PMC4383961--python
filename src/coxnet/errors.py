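"""Exception hierarchy shared across the package."""


class CoxnetError(Exception):
    """Base class for all coxnet errors."""


class DataError(CoxnetError):
    """Malformed or invariant-violating input data."""


class ConfigError(CoxnetError):
    """Invalid configuration or parameter values."""
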