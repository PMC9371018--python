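"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`CatimputeError`, so callers (and the CLI) can catch one type.
"""


class CatimputeError(Exception):
    """Base class for all catimpute errors."""


class SchemaViolationError(CatimputeError):
    """A cell value falls outside its declared attribute domain."""


class CsvParseError(CatimputeError):
    """Malformed CSV input (ragged rows, missing header...)."""


class ConfigError(CatimputeError):
    """Invalid configuration value (rate out of range, bad mechanism tag...)."""


class MissingCellError(CatimputeError):
    """An operation requiring observed cells hit a MISSING cell."""


class LayoutMismatchError(CatimputeError):
    """Matrix width does not match the one-hot layout it is decoded against."""


class ShapeError(CatimputeError):
    """Incompatible array shapes in a numeric operation."""


class DivergenceError(CatimputeError):
    """Non-finite loss or gradient during network training."""


class NoDonorError(CatimputeError):
    """Donor-based imputation with an empty complete-row pool."""


class UnimputableAttributeError(CatimputeError):
    """An attribute with no observed values (or a numeric missing cell)."""


class UnimputableTypeError(CatimputeError):
    """A missing type with no eligible training rows."""


class ReconstructionError(CatimputeError):
    """Row identities overlap or collide when merging table parts."""
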