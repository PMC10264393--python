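"""Laboratory-derived thermal-limit constants and exposure flags.

The defaults are the species' published means: panting threshold (the upper
critical limit surrogate) at a skin temperature of 40.6 °C (body 38.9 °C) and
critical thermal minimum at a skin temperature of 9.9 °C (body 12.1 °C).
Transmitter temperatures track skin temperature, so flagging uses the
skin-scale thresholds; the body-scale values are retained for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ThermalLimits", "exposure_flags", "FLAG_ABOVE", "FLAG_BELOW", "FLAG_NONE"]

FLAG_ABOVE = "above_ctmax"
FLAG_BELOW = "below_ctmin"
FLAG_NONE = "none"


@dataclass(frozen=True)
class ThermalLimits:
    panting_skin: float = 40.6
    panting_body: float = 38.9
    ctmin_skin: float = 9.9
    ctmin_body: float = 12.1

    def __post_init__(self) -> None:
        if self.panting_skin <= self.ctmin_skin:
            raise ValueError("panting_skin must exceed ctmin_skin")
        if self.panting_body <= self.ctmin_body:
            raise ValueError("panting_body must exceed ctmin_body")


def exposure_flags(t_trans, limits: ThermalLimits = ThermalLimits()):
    """Flag transmitter temperatures outside the skin-scale tolerance window.

    Scalar input returns one of ``"above_ctmax"``, ``"below_ctmin"`` or
    ``"none"``; array input returns an object array of the same flags.  The
    flags are mutually exclusive by construction (panting > CTmin).
    """
    t = np.asarray(t_trans, dtype=float)
    out = np.full(t.shape, FLAG_NONE, dtype=object)
    out[t > limits.panting_skin] = FLAG_ABOVE
    out[t < limits.ctmin_skin] = FLAG_BELOW
    if np.ndim(t_trans) == 0:
        return out.item()
    return out
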