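"""Exception hierarchy shared across the toolkit."""


class QsarKitError(Exception):
    """Base class for all qsarkit errors."""


class ParseError(QsarKitError):
    """A molecule entry could not be interpreted."""


class EmptyInputError(QsarKitError):
    """An input file or table contained no usable molecules."""


class AromaticityError(QsarKitError):
    """No valid Kekulé bond assignment exists for an aromatic system."""


class ConfigurationError(QsarKitError):
    """An unknown checker, standardizer, descriptor or option was requested."""


class RuleError(QsarKitError):
    """A custom standardizer pattern failed to parse or apply."""


class MissingValueError(QsarKitError):
    """A descriptor could not be computed for a molecule (e.g. element
    absent from the polarizability table)."""


class ZeroVarianceError(QsarKitError):
    """A feature column is constant; standardization is undefined.

    Run variable reduction first to drop constant columns."""


class SingularMatrixError(QsarKitError):
    """X'X is singular; leverage values are undefined.

    Run variable reduction first to remove collinear columns."""
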