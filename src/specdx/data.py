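"""Core data model for multispectral specimen measurements.

A surgical specimen is probed at ten points: five on the lesion (center
plus four cardinal neighbours) and five at random perilesional sites
roughly 2 cm from the lesion margin.  Each point yields one *spectral
group*: two laser-excited autofluorescence spectra and one broadband
diffuse-reflectance spectrum, every spectrum digitised on a fixed
1,025-point wavelength grid.

Pathology ground truth uses the standard invasiveness ladder for lung
adenocarcinoma -- AAH, AIS, MIA, IAC -- plus benign inflammatory lesions
and normal lung tissue, dichotomised for diagnosis into IAC vs non-IAC.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Sequence

import numpy as np

#: Fixed number of digitised intensity points per spectrum.
SPECTRUM_LENGTH = 1025

#: Number of lesion / perilesional measurement points per specimen.
POINTS_PER_SITE = 5


class Modality(str, enum.Enum):
    FLUORESCENCE = "fluorescence"
    REFLECTANCE = "reflectance"


class Site(str, enum.Enum):
    LESION = "lesion"
    PERILESIONAL = "perilesional"


class BinaryLabel(str, enum.Enum):
    IAC = "IAC"
    NON_IAC = "NON_IAC"


class SpectralClass(str, enum.Enum):
    """Tissue classes on the adenocarcinoma invasiveness spectrum.

    NORMAL is reserved for perilesional tissue; it is never a specimen's
    pathology diagnosis.
    """

    NORMAL = "NORMAL"
    INFLAMMATORY = "INFLAMMATORY"
    AAH = "AAH"
    AIS = "AIS"
    MIA = "MIA"
    IAC = "IAC"

    @property
    def binary_label(self) -> BinaryLabel:
        return BinaryLabel.IAC if self is SpectralClass.IAC else BinaryLabel.NON_IAC

    @property
    def is_invasive(self) -> bool:
        return self is SpectralClass.IAC


#: Classes a specimen's paraffin diagnosis may take.
LESION_CLASSES = (
    SpectralClass.INFLAMMATORY,
    SpectralClass.AAH,
    SpectralClass.AIS,
    SpectralClass.MIA,
    SpectralClass.IAC,
)

#: Pre-/minimally-invasive grades with a defined invasion ordering.
GRADED_CLASSES = (
    SpectralClass.AAH,
    SpectralClass.AIS,
    SpectralClass.MIA,
    SpectralClass.IAC,
)


class FSCall(str, enum.Enum):
    """Intraoperative frozen-section result.

    The pathologist either makes a definite invasive / non-invasive call
    or defers to paraffin (indeterminate).
    """

    DEFINITE_IAC = "DEFINITE_IAC"
    DEFINITE_NON_IAC = "DEFINITE_NON_IAC"
    INDETERMINATE = "INDETERMINATE"


class DataModelError(ValueError):
    """Raised when a domain object violates its structural invariants."""


@dataclasses.dataclass(frozen=True)
class WavelengthGrid:
    """Fixed wavelength axis (nm) for one modality.

    Strictly increasing, exactly :data:`SPECTRUM_LENGTH` points.  The
    reflectance grid must contain 480 nm, the landmark wavelength at
    which normal lung and adenocarcinoma separate most strongly.
    """

    modality: Modality
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (SPECTRUM_LENGTH,):
            raise DataModelError(
                f"wavelength grid must have {SPECTRUM_LENGTH} points, got {pts.shape}"
            )
        if not np.all(np.diff(pts) > 0):
            raise DataModelError("wavelength grid must be strictly increasing")
        if self.modality is Modality.REFLECTANCE and not (pts[0] <= 480.0 <= pts[-1]):
            raise DataModelError("reflectance grid must span 480 nm")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def start(self) -> float:
        return float(self.points[0])

    @property
    def end(self) -> float:
        return float(self.points[-1])

    def nearest_index(self, wavelength: float) -> int:
        """Index of the grid point closest to ``wavelength`` (nm)."""
        return int(np.argmin(np.abs(self.points - wavelength)))


@dataclasses.dataclass
class Spectrum:
    """One modality's digitised intensity vector on a fixed grid.

    Intensities are arbitrary detector units, finite and non-negative.
    """

    grid: WavelengthGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.shape != (SPECTRUM_LENGTH,):
            raise DataModelError(
                f"spectrum must have {SPECTRUM_LENGTH} points, got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise DataModelError("spectrum contains non-finite intensities")
        if np.any(arr < 0):
            raise DataModelError("spectrum contains negative intensities")
        self.intensities = arr

    @property
    def modality(self) -> Modality:
        return self.grid.modality


@dataclasses.dataclass
class SpectralGroup:
    """One measurement point's bundle: 2 fluorescence + 1 reflectance spectra."""

    point_index: int
    site: Site
    fluorescence: tuple[Spectrum, Spectrum]
    reflectance: Spectrum

    def __post_init__(self) -> None:
        if not (1 <= int(self.point_index) <= POINTS_PER_SITE):
            raise DataModelError(
                f"point_index must be in 1..{POINTS_PER_SITE}, got {self.point_index}"
            )
        fl = tuple(self.fluorescence)
        if len(fl) != 2:
            raise DataModelError("a spectral group needs exactly 2 fluorescence spectra")
        for s in fl:
            if s.modality is not Modality.FLUORESCENCE:
                raise DataModelError("fluorescence slot holds a non-fluorescence spectrum")
        if self.reflectance.modality is not Modality.REFLECTANCE:
            raise DataModelError("reflectance slot holds a non-reflectance spectrum")
        self.fluorescence = fl
        self.site = Site(self.site)

    @property
    def spectra(self) -> tuple[Spectrum, Spectrum, Spectrum]:
        """All three spectra in canonical order (fluor 1, fluor 2, reflectance)."""
        return (self.fluorescence[0], self.fluorescence[1], self.reflectance)


@dataclasses.dataclass
class Specimen:
    """A resected specimen: 10 spectral groups plus pathology ground truth."""

    specimen_id: str
    truth_class: SpectralClass
    groups: list[SpectralGroup]
    fs_call: FSCall | None = None
    delay_minutes: float = 0.0

    def __post_init__(self) -> None:
        self.truth_class = SpectralClass(self.truth_class)
        if self.truth_class is SpectralClass.NORMAL:
            raise DataModelError("NORMAL is not a valid specimen diagnosis")
        if self.delay_minutes < 0:
            raise DataModelError("delay_minutes must be non-negative")
        for site in Site:
            idx = sorted(g.point_index for g in self.groups if g.site is site)
            if idx != list(range(1, POINTS_PER_SITE + 1)):
                raise DataModelError(
                    f"specimen {self.specimen_id!r}: {site.value} point indices "
                    f"must be 1..{POINTS_PER_SITE} exactly once, got {idx}"
                )
        if len(self.groups) != 2 * POINTS_PER_SITE:
            raise DataModelError(
                f"specimen {self.specimen_id!r} must have {2 * POINTS_PER_SITE} groups"
            )

    @property
    def lesion_groups(self) -> list[SpectralGroup]:
        return sorted(
            (g for g in self.groups if g.site is Site.LESION), key=lambda g: g.point_index
        )

    @property
    def perilesional_groups(self) -> list[SpectralGroup]:
        return sorted(
            (g for g in self.groups if g.site is Site.PERILESIONAL),
            key=lambda g: g.point_index,
        )

    @property
    def binary_label(self) -> BinaryLabel:
        return self.truth_class.binary_label


def total_groups(cohort: Iterable[Specimen]) -> int:
    return sum(len(s.groups) for s in cohort)


def total_spectra(cohort: Iterable[Specimen]) -> int:
    return sum(len(g.spectra) for s in cohort for g in s.groups)


def cohort_summary(cohort: Sequence[Specimen]) -> dict:
    """Counts used for design-fidelity checks and logging."""
    classes: dict[str, int] = {}
    for s in cohort:
        classes[s.truth_class.value] = classes.get(s.truth_class.value, 0) + 1
    return {
        "n_specimens": len(cohort),
        "n_groups": total_groups(cohort),
        "n_spectra": total_spectra(cohort),
        "class_counts": classes,
    }
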