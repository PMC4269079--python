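"""Exception types shared across the package."""


class DigsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DigsError, ValueError):
    """A text input file violates its format contract."""


class ValidationError(DigsError, ValueError):
    """An in-memory object or argument violates a documented precondition."""


class SolverTimeoutError(DigsError, RuntimeError):
    """The MILP solver hit its time limit without producing any incumbent."""

    def __init__(self, pathway_name: str, time_limit_s: float):
        self.pathway_name = pathway_name
        self.time_limit_s = time_limit_s
        super().__init__(
            f"no feasible incumbent for pathway {pathway_name!r} "
            f"within {time_limit_s:g} s"
        )
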