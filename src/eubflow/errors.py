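"""Exception hierarchy.

Exit codes follow the CLI contract: 2 for configuration problems,
3 for malformed or inconsistent data.
"""


class EubflowError(Exception):
    exit_code = 1


class ConfigError(EubflowError):
    """Invalid configuration, parameters, or missing required inputs."""

    exit_code = 2


class DataError(EubflowError):
    """Malformed, empty, or internally inconsistent data."""

    exit_code = 3
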