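"""Exception hierarchy shared across pipeline stages."""


class GermscreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(GermscreenError):
    """Invalid configuration value; message names the offending field."""


class FormatError(GermscreenError):
    """Malformed or inconsistent input file."""


class EmptyResultError(GermscreenError):
    """A stage produced an empty result where downstream work needs one."""


class DegenerateInputError(GermscreenError):
    """Input lacks the variation an estimator needs (e.g. constant scores)."""
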