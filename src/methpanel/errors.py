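"""Exception hierarchy; exit codes are what the CLI returns."""


class MethPanelError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(MethPanelError):
    """Invalid inputs: malformed sheets, out-of-range betas, bad configs."""

    exit_code = 2


class ConfigurationError(ValidationError):
    """A run/panel configuration that cannot be executed as given."""


class DataError(MethPanelError):
    """Structurally valid inputs that are inconsistent with each other."""

    exit_code = 3
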