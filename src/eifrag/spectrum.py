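"""Peak-list reading, contaminant lists, and annotated-spectrum writing.

Observed spectra are plain-text centroided peak lists: one peak per line,
whitespace- or tab-delimited m/z and intensity columns, ``#`` comments.
Contaminant lists (e.g. protecting-group peaks from peptide synthesis
reagents) are one m/z value per line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import MatchReport

__all__ = [
    "Peak",
    "PeakList",
    "ContaminantList",
    "load_peaks",
    "load_contaminants",
    "packaged_contaminants",
    "write_peaks",
    "write_annotated",
    "CONTAMINANT_SETS",
]

#: Names of the packaged protecting-group contaminant lists.
CONTAMINANT_SETS = ("fmoc", "trt", "pbf", "boc_otbu")


@dataclass(frozen=True, slots=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be nonnegative, got {self.intensity}")


@dataclass
class PeakList:
    """An ordered list of observed (m/z, intensity) peaks."""

    peaks: list[Peak] = field(default_factory=list)
    source_label: str = ""

    @property
    def base_peak_intensity(self) -> float:
        """Intensity of the most intense peak (0 for an empty list)."""
        return max((p.intensity for p in self.peaks), default=0.0)

    @property
    def base_peak_index(self) -> int | None:
        """Index of the single most intense peak (first on ties)."""
        if not self.peaks:
            return None
        return max(range(len(self.peaks)), key=lambda i: (self.peaks[i].intensity, -i))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)


@dataclass
class ContaminantList:
    """Known non-analyte m/z values to mask before scoring."""

    mz_values: list[float]
    label: str = ""

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.mz_values):
            raise ValueError("contaminant m/z values must be positive")
        if len(set(self.mz_values)) != len(self.mz_values):
            raise ValueError("contaminant m/z values must be unique")

    def __len__(self) -> int:
        return len(self.mz_values)


def load_peaks(
    path: str | Path,
    mz_column: int = 0,
    intensity_column: int = 1,
) -> PeakList:
    """Read a whitespace-delimited text peak list, preserving input order.

    Column indices are configurable to accommodate exports with extra
    leading columns. Non-numeric fields raise ValueError with the line
    number; an empty file yields an empty list with a warning.
    """
    p = Path(path)
    peaks = []
    for lineno, raw in enumerate(p.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        needed = max(mz_column, intensity_column) + 1
        if len(fields) < needed:
            raise ValueError(f"{p.name} line {lineno}: expected >= {needed} columns, got {len(fields)}")
        try:
            mz = float(fields[mz_column])
            inten = float(fields[intensity_column])
        except ValueError:
            raise ValueError(f"{p.name} line {lineno}: non-numeric field in {line!r}") from None
        peaks.append(Peak(mz, inten))
    if not peaks:
        warnings.warn(f"peak list {p.name} contains no peaks", stacklevel=2)
    return PeakList(peaks, source_label=p.name)


def load_contaminants(path: str | Path, label: str | None = None) -> ContaminantList:
    """Read a one-m/z-per-line contaminant list (``#`` comments allowed)."""
    p = Path(path)
    vals = []
    for lineno, raw in enumerate(p.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            vals.append(float(line))
        except ValueError:
            raise ValueError(f"{p.name} line {lineno}: non-numeric m/z {line!r}") from None
    return ContaminantList(vals, label=label or p.stem)


def packaged_contaminants(name: str) -> ContaminantList:
    """Load one of the shipped protecting-group peak lists by name.

    Available names: ``fmoc``, ``trt``, ``pbf``, ``boc_otbu``.
    """
    if name not in CONTAMINANT_SETS:
        raise ValueError(f"unknown contaminant set {name!r}; choose from {CONTAMINANT_SETS}")
    p = resources.files("eifrag.data.contaminants").joinpath(f"{name}.txt")
    return load_contaminants(Path(str(p)), label=name)


def write_peaks(peaks: PeakList, out: str | Path) -> None:
    """Write a peak list in the two-column text dialect (4-decimal m/z)."""
    lines = [f"# peak list: {peaks.source_label}", "# m/z\tintensity"]
    for p in peaks:
        lines.append(f"{p.mz:.4f}\t{p.intensity:.4f}")
    Path(out).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_annotated(peaks: PeakList, matches: "MatchReport", out: str | Path) -> None:
    """Write the annotated spectrum: m/z, intensity, annotations.

    Each row lists the matched prediction's m/z and mechanism path, a
    ``contaminant`` flag where applicable, and a ``base_peak`` flag on the
    single most intense peak; unannotated rows are marked ``background``.
    """
    by_index: dict[int, list[str]] = {}
    for pair in matches.pairs:
        tags = by_index.setdefault(pair.peak_index, [])
        tags.append(f"match:{pair.predicted_mz:.4f}[{pair.path}]")
    for idx in matches.contaminant_indices:
        by_index.setdefault(idx, []).append("contaminant")
    base_idx = peaks.base_peak_index
    lines = [
        f"# annotated spectrum: {peaks.source_label}",
        "m/z\tintensity\tannotation",
    ]
    for i, p in enumerate(peaks):
        tags = list(by_index.get(i, []))
        if i == base_idx:
            tags.append("base_peak")
        if not tags:
            tags = ["background"]
        lines.append(f"{p.mz:.4f}\t{p.intensity:.4f}\t{';'.join(tags)}")
    Path(out).write_text("\n".join(lines) + "\n", encoding="utf-8")
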