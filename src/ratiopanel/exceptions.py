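"""Exception hierarchy for ratiopanel.

All package errors derive from :class:`RatioPanelError` so callers can
catch everything this library raises with one clause.
"""


class RatioPanelError(Exception):
    """Base class for all ratiopanel errors."""


class InputFormatError(RatioPanelError, ValueError):
    """A file or table violates the expected format (bad cell, bad shape)."""


class DuplicateIdError(InputFormatError):
    """A species or sample identifier occurs more than once."""


class ValidationError(RatioPanelError, ValueError):
    """Values parsed fine but violate a domain invariant (enum, range)."""


class ConfigError(RatioPanelError, ValueError):
    """A simulation or pipeline configuration is inconsistent."""


class ParameterError(RatioPanelError, ValueError):
    """A function argument is out of its allowed domain."""


class AnnotationError(RatioPanelError, KeyError):
    """A species id has no annotation record."""


class EmptyGroupError(RatioPanelError, ValueError):
    """A group required for a contrast has no samples."""


class DegenerateLabelsError(RatioPanelError, ValueError):
    """A binary analysis received labels from a single class."""


class MissingFeatureError(RatioPanelError, KeyError):
    """A cohort lacks a feature (ncRNA pair) required by a fitted panel."""
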