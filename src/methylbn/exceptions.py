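"""Exception hierarchy shared across the package."""


class MethylBNError(Exception):
    """Base class for all package-specific errors."""


class CycleError(MethylBNError, ValueError):
    """An operation would introduce (or encountered) a directed cycle."""


class InvalidCountError(MethylBNError, ValueError):
    """A count cell is negative or non-integer; message names the cell."""


class MissingConditionError(MethylBNError, ValueError):
    """The condition column is absent from an input table."""


class DuplicateFeatureError(MethylBNError, ValueError):
    """Two columns of an input table share the same name."""


class InvalidConditionError(MethylBNError, ValueError):
    """The condition column holds a value outside {0, 1}."""
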