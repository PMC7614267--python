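"""In-memory containers for peak lists and spectra.

A ``PeakList`` holds fragment (or MS1) peaks plus optional precursor m/z and
fraction metadata (HPLC fraction id, retention time). Single charge is
assumed throughout; deisotoping and charge deconvolution are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class PeakList:
    """Fragment peaks with optional precursor and fraction metadata."""

    peaks: list[Peak] = field(default_factory=list)
    precursor_mz: Optional[float] = None
    polarity: str = "positive"
    spectrum_id: Optional[str] = None
    fraction: Optional[str] = None
    retention_time: Optional[float] = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    def sorted(self) -> "PeakList":
        out = PeakList(
            sorted(self.peaks, key=lambda p: p.mz),
            self.precursor_mz,
            self.polarity,
            self.spectrum_id,
            self.fraction,
            self.retention_time,
        )
        return out

    def base_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def has_peak(self, mz: float, tolerance: float) -> bool:
        return any(abs(p.mz - mz) <= tolerance for p in self.peaks)

    def nearest(self, mz: float) -> Optional[Peak]:
        if not self.peaks:
            return None
        return min(self.peaks, key=lambda p: abs(p.mz - mz))
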