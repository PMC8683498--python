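"""Exception hierarchy.

``InputError`` maps to CLI exit code 2 (unreadable / malformed inputs),
``ModelAssumptionError`` to exit code 3 (data violate a model assumption,
e.g. the pigeonhole sum rule or an inconsistent purity/CCF combination).
"""


class ClonedynError(Exception):
    """Base class for all package errors."""


class InputError(ClonedynError):
    """Malformed or unreadable input (files, tables, configuration)."""


class ModelAssumptionError(ClonedynError):
    """Inputs are readable but violate an assumption of the model."""


class UncoveredSiteError(ClonedynError):
    """A variant site has zero sequencing depth; the caller must decide
    whether to treat it as missing or as absent."""
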