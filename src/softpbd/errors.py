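"""Exception types shared across the package."""


class SoftPBDError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SoftPBDError, ValueError):
    """An argument violates a documented precondition."""


class MeshParseError(SoftPBDError, ValueError):
    """A mesh file could not be parsed.

    ``line`` is the 1-based line number where parsing failed, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TopologyError(SoftPBDError, ValueError):
    """A mesh fails a required topological property (closedness, orientation)."""


class SolverError(SoftPBDError, RuntimeError):
    """The time integrator produced an invalid state (non-finite positions/forces)."""

    def __init__(self, message: str, node: int | None = None, state=None):
        self.node = node
        self.state = state
        if node is not None:
            message = f"{message} (node {node})"
        super().__init__(message)
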