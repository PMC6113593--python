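"""Exception hierarchy for dietledger."""


class DietLedgerError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DietLedgerError):
    """A tabular input is missing required columns or is structurally unusable."""


class DuplicateKeyError(DietLedgerError):
    """Two entries share a key that must be unique (ingredient or dish name)."""


class VocabularyError(DietLedgerError):
    """A token falls outside a controlled vocabulary (dish type, method, category)."""


class RecipeValidationError(DietLedgerError):
    """A recipe violates its invariants (e.g. no non-auxiliary ingredient)."""


class DegenerateRecipeError(DietLedgerError):
    """Decomposition is impossible: total counted ingredient weight is zero."""


class IngredientLookupError(DietLedgerError, KeyError):
    """An ingredient named by a recipe is absent from the composition table."""


class DishLookupError(DietLedgerError, KeyError):
    """A dish name does not resolve in the recipe database."""


class EmptyComparisonError(DietLedgerError):
    """A deviation comparison has no shared nutrients to compare."""
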