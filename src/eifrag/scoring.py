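"""Tolerance matching of observed peaks to predictions and threshold scoring.

A peak matches a prediction when their m/z difference does not exceed the
instrumental tolerance (default ±0.25 Th, boundary inclusive). Peaks that
match a known contaminant value are classed as contaminants first and
excluded from scoring. The fitness score at an intensity threshold t is
the percentage of non-contaminant peaks with intensity >= t × (base peak
intensity) that match at least one prediction; each peak matches at most
its nearest prediction, while one prediction may absorb several peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .engine import PredictionSet
from .spectrum import ContaminantList, PeakList, Peak

__all__ = [
    "MatchPair",
    "MatchReport",
    "ScoreReport",
    "match_peaks",
    "score_spectrum",
    "aggregate_scores",
    "DEFAULT_TOLERANCE",
]

#: Maximum instrumental m/z error used for matching, in Th.
DEFAULT_TOLERANCE = 0.25


@dataclass(frozen=True, slots=True)
class MatchPair:
    peak_index: int
    peak: Peak
    predicted_mz: float
    path: str
    abs_error: float


@dataclass
class MatchReport:
    """Partition of a peak list into matched, unmatched and contaminant peaks."""

    pairs: list[MatchPair] = field(default_factory=list)
    unmatched_indices: list[int] = field(default_factory=list)
    contaminant_indices: list[int] = field(default_factory=list)
    tolerance: float = DEFAULT_TOLERANCE

    @property
    def matched_indices(self) -> list[int]:
        return [p.peak_index for p in self.pairs]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class ScoreReport:
    """Threshold fitness score for one (spectrum, prediction set) pair.

    ``percent_matched`` is 100 × n_matched / n_considered over the peaks
    at or above the intensity threshold after contaminant removal; it is
    None when no peak meets the threshold.
    """

    threshold_fraction: float
    tolerance: float
    n_considered: int
    n_matched: int
    mean_abs_error: float | None
    sd_abs_error: float | None

    @property
    def percent_matched(self) -> float | None:
        if self.n_considered == 0:
            return None
        return 100.0 * self.n_matched / self.n_considered


def _nearest(sorted_mzs: list[tuple[float, str]], mz: float) -> tuple[float, str, float] | None:
    """Nearest predicted m/z to an observed value; ties to the smaller m/z."""
    if not sorted_mzs:
        return None
    import bisect

    i = bisect.bisect_left(sorted_mzs, (mz, ""))
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(sorted_mzs):
            pmz, path = sorted_mzs[j]
            err = abs(pmz - mz)
            if best is None or err < best[2] or (err == best[2] and pmz < best[0]):
                best = (pmz, path, err)
    return best


def match_peaks(
    peaks: PeakList,
    predictions: PredictionSet,
    tolerance: float = DEFAULT_TOLERANCE,
    contaminants: ContaminantList | None = None,
) -> MatchReport:
    """Annotate each observed peak against a prediction set.

    A peak within tolerance of any contaminant value is classed as a
    contaminant and never scored. Remaining peaks match the nearest
    prediction within tolerance (inclusive boundary; ties broken toward
    the smaller absolute error, then the smaller predicted m/z). The
    matched, unmatched and contaminant sets partition the peak list.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    pred = sorted(
        {(round(f.mz, 10), f.path_text) for f in predictions.fragments}
    )
    contam = sorted(contaminants.mz_values) if contaminants else []
    report = MatchReport(tolerance=tolerance)
    for i, pk in enumerate(peaks):
        if contam and any(abs(pk.mz - c) <= tolerance for c in contam):
            report.contaminant_indices.append(i)
            continue
        best = _nearest(pred, pk.mz)
        if best is not None and best[2] <= tolerance:
            report.pairs.append(MatchPair(i, pk, best[0], best[1], best[2]))
        else:
            report.unmatched_indices.append(i)
    return report


def score_spectrum(
    peaks: PeakList,
    predictions: PredictionSet,
    threshold_fraction: float,
    tolerance: float = DEFAULT_TOLERANCE,
    contaminants: ContaminantList | None = None,
) -> ScoreReport:
    """Threshold fitness score of a spectrum against a prediction set.

    Contaminant masking precedes the intensity threshold: peaks flagged as
    contaminants are dropped, then peaks with intensity >= threshold ×
    base-peak intensity are scored. The score is invariant to peak order
    and to rescaling all intensities by a positive constant.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    report = match_peaks(peaks, predictions, tolerance, contaminants)
    # masking precedes thresholding: the base peak is the most intense
    # peak remaining after contaminant removal
    contam = set(report.contaminant_indices)
    base = max(
        (p.intensity for i, p in enumerate(peaks) if i not in contam), default=0.0
    )
    cutoff = threshold_fraction * base
    considered_matched = [p for p in report.pairs if p.peak.intensity >= cutoff]
    n_unmatched = sum(
        1 for i in report.unmatched_indices if peaks.peaks[i].intensity >= cutoff
    )
    n_considered = len(considered_matched) + n_unmatched
    errors = [p.abs_error for p in considered_matched]
    mean = sum(errors) / len(errors) if errors else None
    if errors and len(errors) > 1:
        sd = math.sqrt(sum((e - mean) ** 2 for e in errors) / (len(errors) - 1))
    elif errors:
        sd = 0.0
    else:
        sd = None
    return ScoreReport(
        threshold_fraction=threshold_fraction,
        tolerance=tolerance,
        n_considered=n_considered,
        n_matched=len(considered_matched),
        mean_abs_error=mean,
        sd_abs_error=sd,
    )


def aggregate_scores(reports: list[ScoreReport]) -> dict[str, float | None]:
    """Aggregate fitness scores across several spectra, both ways.

    Returns the unweighted mean of the per-spectrum percentages (each
    spectrum counts equally) and the pooled percentage over all considered
    peaks (each peak counts equally); spectra with no considered peaks are
    excluded. The two differ whenever spectra contribute unequal peak
    counts, so both are reported.
    """
    usable = [r for r in reports if r.n_considered > 0]
    if not usable:
        return {"mean_of_percentages": None, "pooled_percentage": None}
    mean_pct = sum(r.percent_matched for r in usable) / len(usable)
    total_considered = sum(r.n_considered for r in usable)
    total_matched = sum(r.n_matched for r in usable)
    return {
        "mean_of_percentages": mean_pct,
        "pooled_percentage": 100.0 * total_matched / total_considered,
    }
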