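"""Exception and warning hierarchy shared across the package."""


class PlastidegError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PlastidegError, ValueError):
    """A value violates a documented precondition."""


class SchemaError(PlastidegError):
    """An input table is missing mandatory columns or is otherwise malformed."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []


class RowParseError(PlastidegError):
    """One or more rows of an input table failed to parse.

    ``errors`` holds (line_number, message) pairs so all bad rows are
    reported together rather than one at a time.
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {n}: {m}" for n, m in errors)
        super().__init__(f"{len(errors)} row error(s): {lines}")


class UnsupportedElementError(InvalidInputError):
    """A chemical formula contains an element the oxygen-demand model excludes."""

    def __init__(self, element: str):
        self.element = element
        super().__init__(
            f"element {element!r} is not supported: theoretical oxygen demand "
            "is defined for C/H/O monomers only (nitrification is inhibited "
            "in the assay, so N does not enter the oxygen balance)"
        )


class EmptyMarkerError(InvalidInputError):
    """No usable single-copy marker records in an ORF table."""


class ComputationError(PlastidegError):
    """A computation failed on otherwise well-formed input."""


class DataWarning(UserWarning):
    """Data looks unusual but is processed anyway (e.g. mass gain from fouling)."""
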