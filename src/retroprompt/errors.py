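"""Exception hierarchy shared across the package.

Exit-code mapping in the CLI: ConfigError -> 2, DataError (and subclasses)
-> 3, anything else -> 1.
"""


class RetropromptError(Exception):
    """Base class for all package errors."""


class ConfigError(RetropromptError):
    """Invalid configuration value (fractions, cluster counts, ranges...)."""


class DataError(RetropromptError):
    """Problem with input data content."""


class ReactionParseError(DataError):
    """A reaction SMILES line does not have the expected arrow structure."""


class InvalidMoleculeError(DataError):
    """A SMILES string does not parse as a molecule."""


class TokenizationError(DataError):
    """A SMILES string contains spans not covered by the token grammar."""


class LabelError(DataError):
    """A reaction-class label is missing or malformed."""


class DimensionalityError(ConfigError):
    """Requested projection dimension exceeds what the data supports."""
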