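"""Peak-list containers and plain-text readers/writers.

A spectrum is a centroided peak list; profile data and peak picking are
out of scope.  Peak lists on disk are two-column text (m/z, intensity),
whitespace- or comma-separated, with an optional header line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["Peak", "Spectrum", "read_peaklist", "write_peaklist"]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """An ordered peak list with acquisition level and calibration state.

    ``peaks`` are stored sorted ascending by m/z regardless of input
    order.  MS2 spectra must declare the precursor m/z.  ``calibration``
    records the (slope, offset) of the last linear recalibration applied,
    if any, and ``warnings`` collects non-fatal processing notes.
    """

    peaks: tuple[Peak, ...]
    level: str = "MS1"
    precursor_mz: float | None = None
    sample_id: str = ""
    calibrated: bool = False
    calibration: tuple[float, float] | None = None
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.level not in ("MS1", "MS2"):
            raise ValueError(f"level must be 'MS1' or 'MS2', got {self.level!r}")
        if self.level == "MS2" and self.precursor_mz is None:
            raise ValueError("MS2 spectra require a precursor m/z")
        ordered = tuple(sorted(self.peaks, key=lambda p: p.mz))
        object.__setattr__(self, "peaks", ordered)
        object.__setattr__(self, "warnings", tuple(self.warnings))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)

    def with_peaks(self, peaks: Iterable[Peak], **changes) -> "Spectrum":
        return replace(self, peaks=tuple(peaks), **changes)

    def with_warning(self, message: str) -> "Spectrum":
        return replace(self, warnings=self.warnings + (message,))

    def scaled(self, factor: float) -> "Spectrum":
        """Uniformly rescale intensities (classification is invariant to this)."""
        return self.with_peaks(Peak(p.mz, p.intensity * factor) for p in self.peaks)

    @classmethod
    def from_arrays(cls, mzs: Sequence[float], intensities: Sequence[float],
                    **kwargs) -> "Spectrum":
        if len(mzs) != len(intensities):
            raise ValueError("mz and intensity arrays differ in length")
        return cls(peaks=tuple(Peak(float(m), float(i))
                               for m, i in zip(mzs, intensities)), **kwargs)


def _parse_line(line: str) -> tuple[float, float] | None:
    fields = line.replace(",", " ").split()
    if len(fields) < 2:
        raise ValueError(f"expected two columns (m/z, intensity): {line!r}")
    return float(fields[0]), float(fields[1])


def read_peaklist(source, level: str = "MS1", precursor_mz: float | None = None,
                  sample_id: str | None = None) -> Spectrum:
    """Read a two-column (m/z, intensity) text peak list.

    ``source`` may be a path or an open text handle.  A single leading
    header line is skipped if it is not numeric.
    """
    if isinstance(source, (str, Path)):
        name = Path(source).stem
        with open(source) as fh:
            lines = fh.readlines()
    else:
        name = getattr(source, "name", "")
        lines = source.readlines()
    peaks = []
    for i, line in enumerate(lines):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            mz, intensity = _parse_line(line)
        except ValueError:
            if i == 0:  # tolerated header
                continue
            raise
        peaks.append(Peak(mz, intensity))
    return Spectrum(peaks=tuple(peaks), level=level, precursor_mz=precursor_mz,
                    sample_id=sample_id if sample_id is not None else name)


def write_peaklist(spectrum: Spectrum, target) -> None:
    """Write a spectrum as two-column whitespace-delimited text."""
    own = isinstance(target, (str, Path))
    fh = open(target, "w") if own else target
    try:
        for p in spectrum.peaks:
            fh.write(f"{p.mz:.5f}\t{p.intensity:.4f}\n")
    finally:
        if own:
            fh.close()
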