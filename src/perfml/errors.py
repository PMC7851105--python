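"""Exception hierarchy for the perfusion pipeline.

Each pipeline stage raises a specific subclass so the CLI can map failures
to stage-tagged exit codes.
"""


class PerfusionError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ParameterError(PerfusionError, ValueError):
    """A model or design parameter violates its invariants."""

    exit_code = 2


class GridError(PerfusionError, ValueError):
    """Curves are not on a shared uniform time grid."""

    exit_code = 3


class WindowError(PerfusionError, ValueError):
    """A frame window (baseline, dip, search) is out of range."""

    exit_code = 4


class ArrivalNotFoundError(PerfusionError, RuntimeError):
    """No contrast-arrival crossing found in a curve."""

    exit_code = 5


class CorrectionError(PerfusionError, RuntimeError):
    """Dual-bolus AIF correction could not be performed."""

    exit_code = 6


class SaturationError(PerfusionError, ValueError):
    """Signal at or above the saturation ceiling; exact inversion impossible."""

    exit_code = 7


class SingularityError(PerfusionError, ValueError):
    """Deconvolution system is singular (e.g. identically-zero AIF)."""

    exit_code = 8


class DimensionError(PerfusionError, ValueError):
    """Mismatched vector or feature dimensions."""

    exit_code = 9


class FoldError(PerfusionError, ValueError):
    """Cross-validation folds cannot be formed (e.g. single-class data)."""

    exit_code = 10


class FitError(PerfusionError, ValueError):
    """A model fit is degenerate (e.g. zero-variance predictor)."""

    exit_code = 11


class LabelError(PerfusionError, ValueError):
    """Labels are not binary where binary labels are required."""

    exit_code = 12
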