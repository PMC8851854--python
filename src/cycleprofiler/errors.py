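"""Exception hierarchy for the profiler."""


class ProfilerError(Exception):
    """Base class for all package errors."""


class ParseError(ProfilerError):
    """A text input (domtblout, DEFINITION string, table) could not be parsed."""


class ConfigError(ProfilerError):
    """Inconsistent configuration: unknown ids, dangling references, bad thresholds."""
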