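"""Time-curve containers shared by all pipeline stages.

Curves are sampled once per heartbeat on a uniform grid; a curve is a pair
of equal-length vectors (times in seconds, values) plus a role tag.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DimensionError, GridError

__all__ = ["Curve", "SignalIntensityCurve", "ConcentrationCurve", "BaselineWindow"]


def _as_vector(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DimensionError(f"expected a 1-D vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Curve:
    """A sampled time curve on a uniform, increasing grid."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", _as_vector(self.times))
        object.__setattr__(self, "values", _as_vector(self.values))
        if self.times.shape != self.values.shape:
            raise DimensionError(
                f"times/values length mismatch: {len(self.times)} vs {len(self.values)}"
            )
        if len(self.times) >= 2:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise GridError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-12):
                raise GridError("times must be uniformly spaced")
        if not np.all(np.isfinite(self.values)):
            raise DimensionError("curve values must be finite")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise GridError("need at least 2 samples to define a sampling interval")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)

    def with_values(self, values) -> "Curve":
        return replace(self, values=_as_vector(values))


@dataclass(frozen=True)
class SignalIntensityCurve(Curve):
    """MR signal intensity vs. time, arbitrary units, one sample per heartbeat."""


@dataclass(frozen=True)
class ConcentrationCurve(Curve):
    """Contrast-agent concentration vs. time in mmol/L.

    ``role`` distinguishes the tissue curve C_t(t) from the arterial input
    function C_b(t).
    """

    role: str = field(default="tissue")  # "tissue" or "arterial"

    def __post_init__(self):
        super().__post_init__()
        if self.role not in ("tissue", "arterial"):
            raise DimensionError(f"unknown concentration role {self.role!r}")


@dataclass(frozen=True)
class BaselineWindow:
    """Indices [first_frame, last_frame] of the pre-contrast segment (inclusive).

    The default covers frames 0-6: bolus arrival is never earlier than
    ~8 s in the acquisition designs used here, and a longer window makes
    the baseline-noise estimate (and hence the artefact-rule margin) far
    more stable than a minimal one.
    """

    first_frame: int = 0
    last_frame: int = 6

    def __post_init__(self):
        if not (0 <= self.first_frame < self.last_frame):
            from .errors import WindowError

            raise WindowError(
                f"invalid baseline window [{self.first_frame}, {self.last_frame}]"
            )

    def slice(self) -> slice:
        return slice(self.first_frame, self.last_frame + 1)

    def stats(self, values: np.ndarray) -> tuple[float, float]:
        """Baseline mean and standard deviation of ``values`` over the window."""
        if self.last_frame >= len(values):
            from .errors import WindowError

            raise WindowError(
                f"baseline window ends at {self.last_frame} but curve has "
                f"{len(values)} frames"
            )
        seg = np.asarray(values, dtype=float)[self.slice()]
        return float(np.mean(seg)), float(np.std(seg))
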