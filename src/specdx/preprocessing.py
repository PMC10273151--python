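"""Spectrum normalization, QC exclusion rules, and classifier input blocks.

Raw detector intensities are rescaled to a "normalized index" in [0, 1]
(per-spectrum max-normalization; a unit-area alternative is available).
QC mirrors the acquisition protocol's exclusion rules: specimens on the
bench for more than 30 minutes are excluded, as are spectra with
non-finite, all-zero or saturated readings.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from typing import IO, Iterable

import numpy as np

from .data import Modality, Specimen, SpectralGroup, Spectrum, SPECTRUM_LENGTH
from .synthetic import DELAY_LIMIT_MINUTES

__all__ = [
    "NormalizedSpectrum",
    "QCError",
    "QCFlag",
    "QCReport",
    "normalize",
    "qc_flags",
    "group_to_block",
    "write_qc_reports",
]


class QCError(ValueError):
    """A spectrum failed a hard quality check (e.g. non-finite values)."""


@dataclasses.dataclass
class NormalizedSpectrum:
    """Intensity vector rescaled for cross-specimen comparability.

    With the default ``max`` method values lie in [0, 1] with max exactly
    1 unless the input was all-zero (then the output is all-zero and
    ``all_zero`` is set for QC).
    """

    intensities: np.ndarray
    modality: Modality
    method: str = "max"
    all_zero: bool = False


def normalize(spectrum: Spectrum, method: str = "max") -> NormalizedSpectrum:
    """Rescale one spectrum to its normalized-index representation.

    ``max``: divide by the maximum (idempotent, invariant to positive
    scaling).  ``area``: divide by the trapezoidal integral over the
    wavelength axis (values are then per-nm densities, not bounded by 1).
    """
    x = np.asarray(spectrum.intensities, dtype=float)
    if not np.all(np.isfinite(x)):
        raise QCError("cannot normalize a spectrum with non-finite intensities")
    if np.any(x < 0):
        raise QCError("cannot normalize a spectrum with negative intensities")
    if method == "max":
        peak = x.max()
        if peak == 0.0:
            return NormalizedSpectrum(x.copy(), spectrum.modality, method, all_zero=True)
        return NormalizedSpectrum(x / peak, spectrum.modality, method)
    if method == "area":
        area = float(np.trapezoid(x, spectrum.grid.points))
        if area == 0.0:
            return NormalizedSpectrum(x.copy(), spectrum.modality, method, all_zero=True)
        return NormalizedSpectrum(x / area, spectrum.modality, method)
    raise ValueError(f"unknown normalization method {method!r}")


class QCFlag(str, enum.Enum):
    DELAY_EXCEEDED = "DELAY_EXCEEDED"
    ALL_ZERO_SPECTRUM = "ALL_ZERO_SPECTRUM"
    NON_FINITE = "NON_FINITE"
    SATURATED = "SATURATED"


#: Flags that exclude a specimen under the default policy (all of them).
DEFAULT_EXCLUDING_FLAGS = frozenset(QCFlag)


@dataclasses.dataclass
class QCReport:
    specimen_id: str
    flags: frozenset[QCFlag]
    excluded: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "specimen_id": self.specimen_id,
                "flags": sorted(f.value for f in self.flags),
                "excluded": self.excluded,
            }
        )


def qc_flags(
    specimen: Specimen,
    delay_limit: float = DELAY_LIMIT_MINUTES,
    saturation_level: float | None = None,
    excluding: frozenset[QCFlag] = DEFAULT_EXCLUDING_FLAGS,
) -> QCReport:
    """Apply the exclusion rules to one specimen.

    DELAY_EXCEEDED uses a strict inequality: a specimen at exactly the
    30-minute limit is still acceptable.  QC never mutates the spectra.
    """
    flags: set[QCFlag] = set()
    if specimen.delay_minutes > delay_limit:
        flags.add(QCFlag.DELAY_EXCEEDED)
    for g in specimen.groups:
        for sp in g.spectra:
            x = sp.intensities
            if not np.all(np.isfinite(x)):
                flags.add(QCFlag.NON_FINITE)
            elif np.all(x == 0):
                flags.add(QCFlag.ALL_ZERO_SPECTRUM)
            elif saturation_level is not None and np.any(x >= saturation_level):
                flags.add(QCFlag.SATURATED)
    frozen = frozenset(flags)
    return QCReport(
        specimen_id=specimen.specimen_id,
        flags=frozen,
        excluded=bool(frozen & excluding),
    )


def group_to_block(group: SpectralGroup, method: str = "max") -> np.ndarray:
    """Classifier input block for one spectral group.

    Rows are the normalized spectra in canonical order: fluorescence
    replicate 1, fluorescence replicate 2, reflectance.  Shape (3, 1025).
    """
    rows = [normalize(sp, method=method).intensities for sp in group.spectra]
    block = np.stack(rows, axis=0)
    assert block.shape == (3, SPECTRUM_LENGTH)
    return block


def write_qc_reports(reports: Iterable[QCReport], stream: IO[str]) -> None:
    """Emit QC reports as JSON lines."""
    for r in reports:
        stream.write(r.to_json() + "\n")


def qc_cohort(specimens: Iterable[Specimen], **kwargs) -> list[QCReport]:
    return [qc_flags(s, **kwargs) for s in specimens]
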