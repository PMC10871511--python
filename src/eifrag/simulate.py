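"""Seeded synthetic-spectrum generator.

Emulates a crude-sample DEP-EI spectrum of a short peptide: a sampled
subset of the sequence's own predicted fragment peaks (with small Gaussian
m/z jitter), optional protecting-group contaminant peaks, and
uniform-random background peaks over the instrument scan range
(60–350 m/z). Real spectra additionally contain isotope satellites,
unmodelled fragmentation chemistry and intensity structure that this
generator does not attempt to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .engine import PredictionSet, enumerate_fragments
from .mechanisms import MechanismCatalogue, builtin_catalogue
from .scoring import DEFAULT_TOLERANCE
from .spectrum import CONTAMINANT_SETS, Peak, PeakList, packaged_contaminants

__all__ = ["FixtureConfig", "generate_synthetic_spectrum", "SCAN_RANGE"]

#: Instrument scan range in m/z for background peaks and clamping.
SCAN_RANGE = (60.0, 350.0)

_INTENSITY_MODELS = ("log-uniform", "uniform")


@dataclass
class FixtureConfig:
    """Configuration of one synthetic spectrum.

    ``mz_jitter_sd`` defaults to tolerance/3 so planted peaks remain
    matchable at the instrumental tolerance; intensities are drawn from a
    log-uniform model spanning three decades by default, mimicking the
    wide dynamic range of electron-ionization peak heights.
    """

    sequence: str
    fraction_of_predictions_observed: float = 1.0
    mz_jitter_sd: float = DEFAULT_TOLERANCE / 3
    n_background_peaks: int = 0
    contaminant_set: str | None = None
    intensity_model: str = "log-uniform"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fraction_of_predictions_observed <= 1):
            raise ValueError("fraction_of_predictions_observed must be in (0, 1]")
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be nonnegative")
        if self.n_background_peaks < 0:
            raise ValueError("n_background_peaks must be nonnegative")
        if self.contaminant_set is not None and self.contaminant_set not in CONTAMINANT_SETS:
            raise ValueError(
                f"contaminant_set must be one of {CONTAMINANT_SETS}, got {self.contaminant_set!r}"
            )
        if self.intensity_model not in _INTENSITY_MODELS:
            raise ValueError(f"intensity_model must be one of {_INTENSITY_MODELS}")

    @classmethod
    def from_file(cls, path: str | Path) -> "FixtureConfig":
        """Read a key-value config file (``key = value`` per line, # comments)."""
        kwargs: dict = {}
        casts = {
            "sequence": str,
            "fraction_of_predictions_observed": float,
            "mz_jitter_sd": float,
            "n_background_peaks": int,
            "contaminant_set": lambda v: None if v.lower() == "none" else v,
            "intensity_model": str,
            "seed": int,
        }
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value', got {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in casts:
                raise ValueError(f"config line {lineno}: unknown field {key!r}")
            kwargs[key] = casts[key](val)
        if "sequence" not in kwargs:
            raise ValueError("config missing required field 'sequence'")
        return cls(**kwargs)


def _intensities(rng: np.random.Generator, n: int, model: str, scale: float) -> np.ndarray:
    if model == "log-uniform":
        return scale * 10.0 ** rng.uniform(-3, 0, size=n)
    return scale * rng.uniform(0.0, 1.0, size=n)


def generate_synthetic_spectrum(
    cfg: FixtureConfig,
    cat: MechanismCatalogue | None = None,
    predictions: PredictionSet | None = None,
    clamp_to_scan_range: bool = True,
) -> PeakList:
    """Build a reproducible synthetic peak list from a fixture config.

    Samples the configured fraction of the sequence's unique predicted m/z
    values, jitters each with Gaussian noise, assigns intensities from the
    configured model, then appends the named contaminant peaks and
    uniform-random background peaks in the scan range. Identical configs
    (including seed) give identical peak lists.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if predictions is None:
        predictions = enumerate_fragments(cfg.sequence, cat or builtin_catalogue())

    mzs = sorted({round(mz, 6) for mz in predictions.mz_values})
    if clamp_to_scan_range:
        mzs = [m for m in mzs if SCAN_RANGE[0] <= m <= SCAN_RANGE[1]]
    n_take = max(1, int(round(cfg.fraction_of_predictions_observed * len(mzs))))
    take = sorted(rng.choice(len(mzs), size=min(n_take, len(mzs)), replace=False))
    planted = np.asarray([mzs[i] for i in take], dtype=float)
    if cfg.mz_jitter_sd > 0:
        planted = planted + rng.normal(0.0, cfg.mz_jitter_sd, size=planted.size)

    peaks = [
        Peak(float(mz), float(inten))
        for mz, inten in zip(
            planted, _intensities(rng, planted.size, cfg.intensity_model, 1e6)
        )
    ]

    if cfg.contaminant_set is not None:
        contam = packaged_contaminants(cfg.contaminant_set)
        for mz, inten in zip(
            contam.mz_values,
            _intensities(rng, len(contam), cfg.intensity_model, 1e6),
        ):
            peaks.append(Peak(float(mz), float(inten)))

    if cfg.n_background_peaks:
        bg_mz = rng.uniform(*SCAN_RANGE, size=cfg.n_background_peaks)
        bg_int = _intensities(rng, cfg.n_background_peaks, cfg.intensity_model, 1e6)
        peaks.extend(Peak(float(m), float(i)) for m, i in zip(bg_mz, bg_int))

    peaks.sort(key=lambda p: p.mz)
    return PeakList(peaks, source_label=f"synthetic:{cfg.sequence}:seed{cfg.seed}")
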