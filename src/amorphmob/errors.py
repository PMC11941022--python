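"""Exception hierarchy for amorphmob."""


class AmorphMobError(Exception):
    """Base class for all package errors."""


class DomainError(AmorphMobError, ValueError):
    """An input violates a documented precondition (out of physical domain)."""


class TrajectoryFormatError(AmorphMobError, ValueError):
    """A trajectory file is malformed.

    Carries the frame index and line number at which parsing failed,
    when they are known.
    """

    def __init__(self, message: str, *, frame: int | None = None,
                 line: int | None = None):
        loc = []
        if frame is not None:
            loc.append(f"frame {frame}")
        if line is not None:
            loc.append(f"line {line}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.frame = frame
        self.line = line
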