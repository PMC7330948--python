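"""Exception hierarchy for seropanel."""


class SeropanelError(Exception):
    """Base class for all seropanel errors."""


class ValidationError(SeropanelError, ValueError):
    """Invalid inputs, parameters, or table schemas."""


class LeakageError(SeropanelError):
    """Sample identifiers shared between a training phase and a blind phase."""
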