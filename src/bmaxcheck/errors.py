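"""Exception hierarchy for bmaxcheck.

All errors raised by the library derive from :class:`BmaxError` so callers
can catch one base class at corpus-processing boundaries.
"""


class BmaxError(Exception):
    """Base class for all bmaxcheck errors."""


class PDBFormatError(BmaxError):
    """A record could not be parsed or written in fixed-column PDB format.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class EmptyStructureError(BmaxError):
    """The input contained no ATOM records."""


class DegenerateCellError(BmaxError):
    """Unit-cell parameters do not describe a positive-volume cell."""


class UnknownCompositionError(BmaxError):
    """Mass computation hit residues/atoms of unknown chemical composition."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(f"unknown composition for: {self.offenders}")


class ImplausibleContentError(BmaxError):
    """Protein mass exceeds what the unit cell can physically hold."""


class UnsupportedResidueError(BmaxError):
    """Atom typing was asked about a non-standard residue."""


class DegenerateDistributionError(BmaxError):
    """B-factor standardization is undefined (zero spread)."""


class InsufficientDataError(BmaxError):
    """Too few points for a regression fit (n < 3)."""


class DegenerateDesignError(BmaxError):
    """All predictor values identical; the regression design is singular."""


class ResolutionOutOfRangeError(BmaxError):
    """Resolution falls outside the configured resolution bins."""


class UntrimmableError(BmaxError):
    """No subset of atoms can bring the average B under the threshold."""


class SynthSpecError(BmaxError):
    """A synthetic-structure specification is unsatisfiable."""
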