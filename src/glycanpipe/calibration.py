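"""Glucose-unit calibration of HPLC retention times.

Columns are calibrated with a pyridylaminated dextran hydrolysate ladder
(degree of polymerization 2-20); retention is then expressed in glucose
units (g.u.) by piecewise-linear interpolation between the ladder anchors.
Piecewise-linear is chosen over a spline: it is exact at the anchors,
strictly monotone whenever the anchors are, and robust with few anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["CalibrationCurve", "GuValue", "to_gu"]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class GuValue:
    """A glucose-unit value; ``extrapolated`` flags out-of-range retention."""

    value: float
    extrapolated: bool = False

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class CalibrationCurve:
    """Dextran-ladder anchors: (retention time / min, degree of
    polymerization). Anchors must be strictly increasing in both
    coordinates; at least four anchors are required."""

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.anchors) < 4:
            raise CalibrationError("need at least four dextran anchors")
        rts = [a[0] for a in self.anchors]
        dps = [a[1] for a in self.anchors]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise CalibrationError("anchor retention times must strictly increase")
        if any(b <= a for a, b in zip(dps, dps[1:])):
            raise CalibrationError("anchor glucose units must strictly increase")

    @classmethod
    def from_table(cls, rows: Sequence[tuple[float, float]]) -> "CalibrationCurve":
        return cls(tuple(sorted((float(r), float(d)) for r, d in rows)))

    def to_gu(self, rt: float) -> GuValue:
        """Map a retention time to glucose units.

        Exact at the anchors; linear between them; outside the calibrated
        range the terminal segment slope is extended and the result is
        flagged as extrapolated.
        """
        rts = np.array([a[0] for a in self.anchors])
        dps = np.array([a[1] for a in self.anchors])
        if rt < rts[0]:
            slope = (dps[1] - dps[0]) / (rts[1] - rts[0])
            return GuValue(float(dps[0] + (rt - rts[0]) * slope), True)
        if rt > rts[-1]:
            slope = (dps[-1] - dps[-2]) / (rts[-1] - rts[-2])
            return GuValue(float(dps[-1] + (rt - rts[-1]) * slope), True)
        return GuValue(float(np.interp(rt, rts, dps)), False)


def to_gu(rt: float, curve: CalibrationCurve) -> GuValue:
    return curve.to_gu(rt)
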