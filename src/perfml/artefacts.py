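"""Dark-rim artefact labeling rule.

A tissue enhancement curve is labeled artefacted when its signal drops
below the pre-contrast baseline at contrast arrival and subsequently
rises. "Below the baseline" is operationalized noise-robustly as below
baseline_mean − m_sd·baseline_sd within a finite search window after the
LV-detected arrival frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import BaselineWindow, SignalIntensityCurve
from .errors import ParameterError, WindowError

__all__ = ["ArtefactRuleConfig", "label_artefact"]


@dataclass(frozen=True)
class ArtefactRuleConfig:
    baseline: BaselineWindow = field(default_factory=BaselineWindow)
    drop_margin: float = 2.0  # in baseline-sd units
    search_window: int = 10  # frames after arrival
    require_rebound: bool = True

    def __post_init__(self):
        if self.drop_margin < 0:
            raise ParameterError("drop_margin must be >= 0")
        if self.search_window < 1:
            raise ParameterError("search_window must be >= 1")


def label_artefact(
    tissue_si: SignalIntensityCurve,
    arrival_frame: int,
    cfg: ArtefactRuleConfig | None = None,
) -> bool:
    """True iff the curve dips below baseline at arrival and later rebounds."""
    cfg = cfg or ArtefactRuleConfig()
    values = np.asarray(tissue_si.values, dtype=float)
    n = len(values)
    if not 0 <= arrival_frame < n:
        raise WindowError(f"arrival_frame {arrival_frame} outside the {n}-frame curve")
    if cfg.baseline.last_frame >= arrival_frame:
        raise WindowError("baseline window must precede the arrival frame")
    mean, sd = cfg.baseline.stats(values)
    lo = min(arrival_frame + cfg.search_window + 1, n)
    window = values[arrival_frame:lo]
    below = window < mean - cfg.drop_margin * sd
    if not np.any(below):
        return False
    if not cfg.require_rebound:
        return True
    dip_frame = arrival_frame + int(np.argmax(below))
    return bool(np.any(values[dip_frame + 1 :] > mean))
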