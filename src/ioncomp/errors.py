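"""Exception hierarchy shared across the compiler pipeline."""


class IoncompError(Exception):
    """Base class for all errors raised by this package."""


class SyntaxErrorWithLocation(IoncompError):
    """Lexical or syntactic error, carrying a 1-based line/column."""

    def __init__(self, message, line=None, column=None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class GrammarError(IoncompError):
    """Well-formed tree, but a construct outside the accepted grammar."""


class RedefinitionError(IoncompError):
    """A name bound twice in the same environment."""


class OutputContractError(IoncompError):
    """A component declares an output it does not define."""


class StructuralError(IoncompError):
    """Model violates the component structuring rules."""


class WiringError(IoncompError):
    """An `input (x from type name)` declaration cannot be resolved."""


class AmbiguityError(WiringError):
    """Input wiring matched several candidate outputs."""


class UnresolvedReferenceError(IoncompError):
    """An identifier resolves in no enclosing scope and is not reserved."""


class CycleError(IoncompError):
    """Circular dependency among algebraic assignments or relations."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("circular dependency: " + " -> ".join(self.cycle))


class NamingError(IoncompError):
    """An identifier cannot be mangled into a target-legal name."""


class EvaluationError(IoncompError):
    """Unbound symbol or arity mismatch during expression evaluation."""


class IntegrationError(IoncompError):
    """The reference integrator failed; message carries the diagnostic."""


class InitializationError(IoncompError):
    """Steady-state initialization could not be computed."""


class ValidationError(IoncompError):
    """Parameter values outside their documented domain."""


class EmptySystemError(IoncompError):
    """A model that lowers to zero differential equations."""
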