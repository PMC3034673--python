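"""Exception hierarchy shared across the package."""


class HalofbaError(Exception):
    """Base class for all package errors."""


class StructuralError(HalofbaError):
    """A model violates a structural invariant (dangling references, bad bounds...)."""


class UnknownReactionError(HalofbaError, KeyError):
    """A reaction id does not resolve in the model."""


class UndefinedRatioError(HalofbaError, ZeroDivisionError):
    """A ratio over an empty denominator set was requested."""


class EquationParseError(HalofbaError, ValueError):
    """A reaction-equation string does not match the grammar.

    Carries ``column``, the 0-based offset of the offending token.
    """

    def __init__(self, message: str, column: int | None = None):
        super().__init__(message if column is None else f"{message} (column {column})")
        self.column = column


class FormulaError(HalofbaError, ValueError):
    """An elemental formula string could not be parsed."""


class GPRParseError(HalofbaError, ValueError):
    """A gene-association boolean expression is malformed."""


class LoadError(HalofbaError):
    """A model file could not be loaded; ``problems`` lists every offending row."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("model load failed:\n" + "\n".join(f"  - {p}" for p in self.problems))


class SchemaVersionError(HalofbaError):
    """A JSON document declares an unsupported schema version."""


class MediumError(HalofbaError):
    """A requested medium component has no uptake route in the model."""


class PathwayError(HalofbaError):
    """A required pathway reaction is missing from the model."""


class InfeasibleError(HalofbaError):
    """The LP constraints are mutually contradictory."""


class UnboundedError(HalofbaError):
    """The LP objective is unbounded under the given constraints."""
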