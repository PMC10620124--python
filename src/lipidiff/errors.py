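"""Exception hierarchy for the pipeline.

All pipeline-specific failures derive from :class:`LipidiffError` so callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class LipidiffError(Exception):
    """Base class for all pipeline errors."""


class NomenclatureError(LipidiffError):
    """A lipid shorthand name could not be parsed."""


class UnknownClassError(NomenclatureError):
    """The class token of a shorthand name is not in the ontology."""


class ArityError(NomenclatureError):
    """The number of chains does not match the lipid class."""


class SchemaError(LipidiffError):
    """Input files disagree with each other or with the expected layout."""


class ValidationError(LipidiffError):
    """Arguments or data violate a precondition."""


class DegenerateSampleError(LipidiffError):
    """A sample has no usable values (all missing, or zero total)."""
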