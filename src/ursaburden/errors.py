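"""Exception hierarchy for ursaburden."""


class UrsaburdenError(Exception):
    """Base class for all ursaburden errors."""


class ConfigurationError(UrsaburdenError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(UrsaburdenError):
    """Input tables are internally inconsistent (e.g. unknown sample ids)."""


class AnalysisError(UrsaburdenError):
    """An analysis cannot be run (e.g. empty case or control stratum)."""


class ModelError(UrsaburdenError):
    """A model fit is impossible (rank deficiency, no outcome variation)."""


class ParseError(UrsaburdenError):
    """A file could not be parsed; the message carries the line number."""
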