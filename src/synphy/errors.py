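"""Exception hierarchy shared across the package."""


class SynphyError(Exception):
    """Base class for all package errors."""


class ParseError(SynphyError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class IntegrityError(SynphyError):
    """Data violates an internal invariant (duplicate ids, unlocatable genes)."""


class InputError(SynphyError):
    """Arguments are inconsistent with each other or with the data."""


class ReplayError(SynphyError):
    """A simulated event could not be re-applied; carries the event index."""

    def __init__(self, message: str, index: int):
        super().__init__(f"event {index}: {message}")
        self.index = index
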