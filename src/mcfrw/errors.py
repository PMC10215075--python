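"""Exception types raised by mcfrw."""


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class GeometryError(ValueError):
    """A geometric configuration is infeasible (e.g. negative axial gap)."""


class TrappedWalkerError(RuntimeError):
    """A walker exceeded the consecutive-rejection bound.

    Carries the position at which the walker was stuck.
    """

    def __init__(self, position, n_rejections):
        self.position = tuple(float(c) for c in position)
        self.n_rejections = int(n_rejections)
        super().__init__(
            f"walker trapped at {self.position} after "
            f"{self.n_rejections} consecutive rejected moves"
        )


class UndefinedTortuosityError(ValueError):
    """Tortuosity is undefined (coincident start and end points)."""
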