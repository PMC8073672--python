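"""Exception types raised across the package."""

from __future__ import annotations


class InvalidGeometryError(ValueError):
    """Inclusion geometry lies (partly) outside the simulated scene."""


class FormatError(ValueError):
    """An on-disk file does not conform to its declared format."""


class AmbiguousIsoPointError(RuntimeError):
    """The sensitivity spectrum has several well-separated sign changes.

    Attributes
    ----------
    candidates
        Candidate iso-point wavelengths (nm), one per sign change.
    """

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            "ambiguous iso-point: multiple well-separated sign changes at "
            + ", ".join(f"{c:.1f} nm" for c in self.candidates)
        )


class EmptyProfileError(ValueError):
    """The requested profile line does not intersect the inclusion mask."""


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class OutOfRangeError(ValueError):
    """A depth-parameter value is unreachable by the calibrated mapping."""
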