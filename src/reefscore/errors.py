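"""Exception hierarchy shared across the package."""

from __future__ import annotations


class ReefscoreError(Exception):
    """Base class for all package-specific errors."""


class DesignValidationError(ReefscoreError):
    """A reef-unit design violates one or more geometric invariants.

    Carries the full list of violations so callers can report them all at
    once rather than fixing one field at a time.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid design: " + "; ".join(self.violations)
        )


class DesignParseError(ReefscoreError):
    """A design file could not be parsed (malformed YAML/JSON or bad schema)."""


class UndefinedIndexError(ReefscoreError):
    """A partial index is undefined because the reference design does not
    contribute to that dimension (zero exposed area, zero upwelling surface
    or no nest cavities)."""

    def __init__(self, dimension: str, detail: str):
        self.dimension = dimension
        super().__init__(f"{dimension} index undefined: {detail}")


class WaveTheoryError(ReefscoreError):
    """Wave-kinematics parameter solve failed (e.g. the cnoidal elliptic
    parameter could not be bracketed)."""


class SlabInfeasibleError(ReefscoreError):
    """No slab height below the configured maximum satisfies the target
    safety factors; names the limiting failure mode."""

    def __init__(self, limiting_mode: str, max_height: float):
        self.limiting_mode = limiting_mode
        self.max_height = max_height
        super().__init__(
            f"no slab height <= {max_height:g} m reaches the target "
            f"{limiting_mode} safety factor"
        )
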