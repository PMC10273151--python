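"""Synthetic multispectral cohort generator.

No raw clinical spectra from the underlying study were ever released, so
this module generates cohorts that reproduce the study's *design*:

* each specimen contributes 10 spectral groups (5 lesion points + 5
  perilesional points), each group holding 2 fluorescence spectra and 1
  reflectance spectrum of 1,025 points;
* class-mean spectra are smooth positive baselines plus Gaussian peaks,
  shaped so that (a) the normal-vs-IAC reflectance difference is maximal
  at 480 nm, and (b) a fluorescence red/green peak-amplitude ratio rises
  monotonically along the invasion ladder AAH < AIS < MIA < IAC, with
  inflammatory lesions overlapping the invasive range (fluorescence alone
  separates inflammation from invasion only weakly);
* lesion points are focal: each point's spectrum is a convex admixture of
  the lesion class mean and the normal-tissue mean, with Beta-distributed
  admixture shared across that point's three spectra.  Minimally invasive
  lesions therefore yield intermediate, widely spread infiltration
  indices while frankly invasive lesions mostly read invasive;
* a simulated frozen-section rater abstains (indeterminate) at the
  study's observed rate and errs on definite calls at the study's
  observed rate;
* specimens delayed on the bench lose lesion/perilesional contrast
  (means shrink toward their common average), mirroring the reported
  failure mode of specimens arriving later than 30 minutes.

Biological realism knobs beyond the Gaussian-peak means: per-point
lognormal jitter of peak amplitudes (biochemical heterogeneity -- this
is what makes MIA vs IAC genuinely ambiguous rather than separable by
an arbitrarily sharp classifier), a smooth specimen-level background
curve and a multiplicative specimen gain (patient/handling variation),
and additive detector noise clipped at zero.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .data import (
    GRADED_CLASSES,
    LESION_CLASSES,
    POINTS_PER_SITE,
    SPECTRUM_LENGTH,
    FSCall,
    Modality,
    Site,
    SpectralClass,
    SpectralGroup,
    Specimen,
    Spectrum,
    WavelengthGrid,
)

__all__ = [
    "GeneratorConfig",
    "ConfigurationError",
    "class_mean_curve",
    "fluorescence_peak_ratio",
    "sample_specimen",
    "sample_cohort",
    "simulate_fs_call",
    "degrade_specimen",
    "default_grids",
]


class ConfigurationError(ValueError):
    """Invalid or incomplete generator configuration."""


# ---------------------------------------------------------------------------
# Default spectral model
# ---------------------------------------------------------------------------

#: Wavelength ranges (nm).  380-780 nm puts 480 nm exactly on the
#: 1,025-point reflectance grid (380 + 256 * 400/1024); fluorescence covers
#: the visible emission band above a ~440 nm laser excitation.
DEFAULT_GRID_RANGES: dict[Modality, tuple[float, float]] = {
    Modality.REFLECTANCE: (380.0, 780.0),
    Modality.FLUORESCENCE: (450.0, 750.0),
}

#: Baseline per modality: (offset, amplitude, center nm, width nm).
DEFAULT_BASELINES: dict[Modality, tuple[float, float, float, float]] = {
    Modality.REFLECTANCE: (0.40, 0.25, 640.0, 110.0),
    Modality.FLUORESCENCE: (0.06, 0.04, 560.0, 120.0),
}

# Gaussian peaks (center nm, width nm, amplitude) per class and modality.
# Reflectance: the 480 nm band is strong in normal lung and fades with
# invasion; a second band near 600 nm moves little.  Fluorescence: a green
# band at 510 nm and a red band at 635 nm whose amplitude ratio grades
# invasion; inflammatory tissue sits inside the MIA-IAC ratio range.
DEFAULT_PEAKS: dict[Modality, dict[SpectralClass, tuple[tuple[float, float, float], ...]]] = {
    Modality.REFLECTANCE: {
        SpectralClass.NORMAL: ((480.0, 40.0, 0.50), (600.0, 60.0, 0.15)),
        SpectralClass.INFLAMMATORY: ((480.0, 40.0, 0.30), (600.0, 60.0, 0.22)),
        SpectralClass.AAH: ((480.0, 40.0, 0.27), (600.0, 60.0, 0.18)),
        SpectralClass.AIS: ((480.0, 40.0, 0.23), (600.0, 60.0, 0.18)),
        SpectralClass.MIA: ((480.0, 40.0, 0.17), (600.0, 60.0, 0.20)),
        SpectralClass.IAC: ((480.0, 40.0, 0.12), (600.0, 60.0, 0.22)),
    },
    Modality.FLUORESCENCE: {
        SpectralClass.NORMAL: ((510.0, 30.0, 1.00), (635.0, 25.0, 0.08)),
        SpectralClass.INFLAMMATORY: ((510.0, 30.0, 0.90), (635.0, 25.0, 0.50)),
        SpectralClass.AAH: ((510.0, 30.0, 1.00), (635.0, 25.0, 0.22)),
        SpectralClass.AIS: ((510.0, 30.0, 1.00), (635.0, 25.0, 0.36)),
        SpectralClass.MIA: ((510.0, 30.0, 1.00), (635.0, 25.0, 0.52)),
        SpectralClass.IAC: ((510.0, 30.0, 1.00), (635.0, 25.0, 0.70)),
    },
}

#: Reference wavelengths of the fluorescence green/red bands used for the
#: graded peak-amplitude ratio.
FLUOR_RATIO_BANDS = (510.0, 635.0)

#: Class mix over specimen diagnoses (non-NORMAL), chosen to mirror the
#: study cohorts' pathology distribution at the stage level: ~40% frankly
#: invasive, the rest spread over the pre-/minimally-invasive ladder with
#: a small benign-inflammatory fraction.
DEFAULT_CLASS_MIX: dict[SpectralClass, float] = {
    SpectralClass.INFLAMMATORY: 0.06,
    SpectralClass.AAH: 0.10,
    SpectralClass.AIS: 0.22,
    SpectralClass.MIA: 0.22,
    SpectralClass.IAC: 0.40,
}

# Beta(a, b) for the specimen-level admixture of lesion-class signal with
# normal tissue (m = fraction of normal).  Pre-invasive lesions are mostly
# normal-like at the probed points; MIA is focal with a wide spread; IAC is
# predominantly tumour signal.  A float instead of a pair pins the
# admixture to that constant (used for degenerate test configurations).
DEFAULT_FOCAL_MIXING: dict[SpectralClass, tuple[float, float] | float] = {
    SpectralClass.INFLAMMATORY: (2.0, 2.0),
    SpectralClass.AAH: (4.0, 1.3),
    SpectralClass.AIS: (3.2, 1.6),
    SpectralClass.MIA: (2.0, 1.4),
    SpectralClass.IAC: (1.0, 6.0),
}


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((x - center) / width) ** 2))


@dataclasses.dataclass
class GeneratorConfig:
    """Everything needed to generate a cohort reproducibly.

    Defaults are the study conditions: 116-specimen modeling cohorts,
    frozen-section indeterminate rate 12/40 = 0.30 and definite-call
    error rate 1/28, 480 nm reflectance landmark, monotone fluorescence
    grading.  Quantities the study does not state (noise, jitter,
    admixture shapes, wavelength ranges) are fixed, documented choices.
    """

    n_specimens: int = 116
    class_mix: dict[SpectralClass, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    grid_ranges: dict[Modality, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GRID_RANGES)
    )
    baselines: dict[Modality, tuple[float, float, float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    peaks: dict[Modality, dict[SpectralClass, tuple[tuple[float, float, float], ...]]] = (
        dataclasses.field(
            default_factory=lambda: {m: dict(t) for m, t in DEFAULT_PEAKS.items()}
        )
    )
    focal_mixing: dict[SpectralClass, tuple[float, float] | float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FOCAL_MIXING)
    )
    #: Concentration of per-point Beta jitter around the specimen-level
    #: admixture mean (larger = points more alike within a specimen).
    point_mixing_concentration: float = 24.0
    #: sd of additive detector noise (intensity units, clipped at zero).
    noise_sd: float = 0.02
    #: sd of the lognormal multiplicative specimen gain.
    specimen_effect_sd: float = 0.15
    #: sd of the smooth additive specimen background curve.
    background_sd: float = 0.04
    #: sd of the per-point lognormal jitter on peak amplitudes.
    amplitude_jitter_sd: float = 0.12
    #: Frozen-section rater: abstention and definite-call error rates.
    fs_indeterminate_prob: float = 0.30
    fs_definite_error_prob: float = 1.0 / 28.0
    #: Bench delay (min) drawn uniformly from this range; the standard
    #: acquisition protocol keeps specimens well under the 30 min limit.
    delay_range: tuple[float, float] = (5.0, 25.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_specimens < 1:
            raise ConfigurationError("n_specimens must be >= 1")
        if not self.class_mix:
            raise ConfigurationError("class_mix must not be empty")
        if SpectralClass.NORMAL in self.class_mix:
            raise ConfigurationError("class_mix must not contain NORMAL")
        weights = np.array(list(self.class_mix.values()), dtype=float)
        if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
            raise ConfigurationError("class_mix must be non-negative and sum to 1")
        for p in (self.fs_indeterminate_prob, self.fs_definite_error_prob):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError("FS probabilities must be in [0, 1]")
        for v in (
            self.noise_sd,
            self.specimen_effect_sd,
            self.background_sd,
            self.amplitude_jitter_sd,
        ):
            if v < 0:
                raise ConfigurationError("noise/effect standard deviations must be >= 0")

    def grid(self, modality: Modality) -> WavelengthGrid:
        start, end = self.grid_ranges[Modality(modality)]
        return WavelengthGrid(
            Modality(modality), np.linspace(start, end, SPECTRUM_LENGTH)
        )


def default_grids() -> dict[Modality, WavelengthGrid]:
    cfg = GeneratorConfig()
    return {m: cfg.grid(m) for m in Modality}


# ---------------------------------------------------------------------------
# Class means
# ---------------------------------------------------------------------------

def _mean_intensities(
    config: GeneratorConfig,
    cls: SpectralClass,
    modality: Modality,
    amplitude_factors: Sequence[float] | None = None,
) -> np.ndarray:
    try:
        peak_table = config.peaks[modality]
    except KeyError as exc:
        raise ConfigurationError(f"no peak table for modality {modality!r}") from exc
    try:
        peaks = peak_table[cls]
    except KeyError as exc:
        raise ConfigurationError(
            f"no peaks configured for class {cls!r} / {modality.value}"
        ) from exc
    offset, amp, center, width = config.baselines[modality]
    lam = config.grid(modality).points
    y = offset + amp * _gauss(lam, center, width)
    if amplitude_factors is None:
        amplitude_factors = np.ones(len(peaks))
    for (c, w, a), f in zip(peaks, amplitude_factors):
        y = y + a * f * _gauss(lam, c, w)
    return y


def class_mean_curve(
    config: GeneratorConfig, cls: SpectralClass, modality: Modality
) -> Spectrum:
    """Noiseless class-mean spectrum: smooth positive baseline + Gaussian peaks.

    Under the default configuration the absolute reflectance difference
    between NORMAL and IAC peaks at the grid point nearest 480 nm, and
    the fluorescence red/green peak ratio increases strictly along
    AAH < AIS < MIA < IAC.
    """
    cls = SpectralClass(cls)
    modality = Modality(modality)
    return Spectrum(config.grid(modality), _mean_intensities(config, cls, modality))


def fluorescence_peak_ratio(config: GeneratorConfig, cls: SpectralClass) -> float:
    """Red/green fluorescence amplitude ratio of a class mean.

    Evaluated at the two reference band centers (635 nm / 510 nm); this
    is the designated scalar that grades invasion monotonically.
    """
    spec = class_mean_curve(config, cls, Modality.FLUORESCENCE)
    i_green = spec.grid.nearest_index(FLUOR_RATIO_BANDS[0])
    i_red = spec.grid.nearest_index(FLUOR_RATIO_BANDS[1])
    return float(spec.intensities[i_red] / spec.intensities[i_green])


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _draw_admixture_mean(
    config: GeneratorConfig, cls: SpectralClass, rng: np.random.Generator
) -> float:
    spec = config.focal_mixing.get(cls)
    if spec is None:
        raise ConfigurationError(f"no focal_mixing entry for class {cls!r}")
    if isinstance(spec, (int, float)):
        return float(spec)
    a, b = spec
    return float(rng.beta(a, b))


def _draw_point_admixture(
    config: GeneratorConfig, mu: float, rng: np.random.Generator, fixed: bool
) -> float:
    if fixed:
        return mu
    kappa = config.point_mixing_concentration
    mu = min(max(mu, 0.02), 0.98)
    return float(rng.beta(mu * kappa, (1.0 - mu) * kappa))


def _specimen_background(
    config: GeneratorConfig, rng: np.random.Generator
) -> dict[Modality, np.ndarray]:
    """Smooth random additive curve shared by all of a specimen's spectra.

    A tilt plus one broad bump; the same functional draw is evaluated on
    both modality grids so the signature is consistent across channels.
    """
    z_off, z_tilt, z_bump = rng.normal(0.0, 1.0, size=3)
    bump_center = rng.uniform(430.0, 730.0)
    out: dict[Modality, np.ndarray] = {}
    for m in Modality:
        lam = config.grid(m).points
        span = lam[-1] - lam[0]
        t = (lam - lam.mean()) / span
        out[m] = config.background_sd * (
            z_off + z_tilt * t + z_bump * _gauss(lam, bump_center, 80.0)
        )
    return out


def sample_specimen(
    config: GeneratorConfig,
    cls: SpectralClass,
    rng: np.random.Generator,
    specimen_id: str = "S000",
    fs_call: FSCall | None = None,
) -> Specimen:
    """Draw one specimen of diagnosis ``cls`` (non-NORMAL).

    Perilesional points follow the NORMAL mean; lesion points mix the
    class mean with the NORMAL mean point-wise by an admixture fraction
    m ~ Beta (specimen-correlated), shared across the point's three
    spectra.  Peak-amplitude jitter, a specimen background curve, a
    multiplicative specimen gain and additive clipped Gaussian noise are
    applied on top.
    """
    cls = SpectralClass(cls)
    if cls is SpectralClass.NORMAL:
        raise ValueError("sample_specimen requires a non-NORMAL diagnosis")
    config.validate()

    gain = float(np.exp(rng.normal(0.0, config.specimen_effect_sd))) if (
        config.specimen_effect_sd > 0
    ) else 1.0
    background = _specimen_background(config, rng)
    mixing_spec = config.focal_mixing.get(cls)
    fixed_mix = isinstance(mixing_spec, (int, float))
    mu_spec = _draw_admixture_mean(config, cls, rng)

    grids = {m: config.grid(m) for m in Modality}
    groups: list[SpectralGroup] = []
    for site in (Site.LESION, Site.PERILESIONAL):
        for point in range(1, POINTS_PER_SITE + 1):
            point_means: dict[Modality, np.ndarray] = {}
            if site is Site.LESION:
                m_p = _draw_point_admixture(config, mu_spec, rng, fixed_mix)
            for modality in Modality:
                n_peaks_cls = len(config.peaks[modality][cls])
                n_peaks_nrm = len(config.peaks[modality][SpectralClass.NORMAL])
                jit_cls = np.exp(
                    rng.normal(0.0, config.amplitude_jitter_sd, size=n_peaks_cls)
                )
                jit_nrm = np.exp(
                    rng.normal(0.0, config.amplitude_jitter_sd, size=n_peaks_nrm)
                )
                normal_mean = _mean_intensities(
                    config, SpectralClass.NORMAL, modality, jit_nrm
                )
                if site is Site.LESION:
                    cls_mean = _mean_intensities(config, cls, modality, jit_cls)
                    mean = (1.0 - m_p) * cls_mean + m_p * normal_mean
                else:
                    mean = normal_mean
                point_means[modality] = gain * (mean + background[modality])

            def _noisy(modality: Modality) -> Spectrum:
                y = point_means[modality]
                if config.noise_sd > 0:
                    y = y + rng.normal(0.0, config.noise_sd, size=SPECTRUM_LENGTH)
                return Spectrum(grids[modality], np.clip(y, 0.0, None))

            groups.append(
                SpectralGroup(
                    point_index=point,
                    site=site,
                    fluorescence=(
                        _noisy(Modality.FLUORESCENCE),
                        _noisy(Modality.FLUORESCENCE),
                    ),
                    reflectance=_noisy(Modality.REFLECTANCE),
                )
            )

    delay = float(rng.uniform(*config.delay_range))
    return Specimen(
        specimen_id=specimen_id,
        truth_class=cls,
        groups=groups,
        fs_call=fs_call,
        delay_minutes=delay,
    )


def simulate_fs_call(
    truth: SpectralClass, config: GeneratorConfig, rng: np.random.Generator
) -> FSCall:
    """Simulated frozen-section rater.

    Abstains (INDETERMINATE) with probability ``fs_indeterminate_prob``;
    otherwise makes a definite call that is wrong (binary label flipped)
    with probability ``fs_definite_error_prob``.
    """
    config.validate()
    truth = SpectralClass(truth)
    if rng.random() < config.fs_indeterminate_prob:
        return FSCall.INDETERMINATE
    correct = truth.is_invasive
    if rng.random() < config.fs_definite_error_prob:
        correct = not correct
    return FSCall.DEFINITE_IAC if correct else FSCall.DEFINITE_NON_IAC


def sample_cohort(
    config: GeneratorConfig,
    seed: int | None = None,
    with_fs: bool = False,
) -> list[Specimen]:
    """Draw a cohort of ``config.n_specimens`` specimens.

    Deterministic for a fixed config and seed (``config.seed`` when no
    seed is passed).  ``with_fs=True`` attaches a simulated
    frozen-section call to every specimen (validation-arm design).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    classes = list(config.class_mix.keys())
    weights = np.array([config.class_mix[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    cohort: list[Specimen] = []
    width = max(3, len(str(config.n_specimens)))
    for i in range(config.n_specimens):
        cls = classes[int(rng.choice(len(classes), p=weights))]
        fs = simulate_fs_call(cls, config, rng) if with_fs else None
        cohort.append(
            sample_specimen(config, cls, rng, specimen_id=f"S{i + 1:0{width}d}", fs_call=fs)
        )
    return cohort


# ---------------------------------------------------------------------------
# Degradation artifact
# ---------------------------------------------------------------------------

#: Bench-delay threshold (min) beyond which specimens degrade / are excluded.
DELAY_LIMIT_MINUTES = 30.0

#: Time constant (min) of contrast loss beyond the delay limit.
DEGRADATION_TAU_MINUTES = 20.0


def degradation_shrinkage(delay_minutes: float) -> float:
    """Fraction by which spectra shrink toward the specimen average.

    Zero at or below the 30 min limit, approaching 1 for long delays
    (lesion and perilesional tissue become indistinguishable).
    """
    if delay_minutes < 0:
        raise ValueError("delay_minutes must be non-negative")
    if delay_minutes <= DELAY_LIMIT_MINUTES:
        return 0.0
    return 1.0 - math.exp(-(delay_minutes - DELAY_LIMIT_MINUTES) / DEGRADATION_TAU_MINUTES)


def degrade_specimen(specimen: Specimen, delay_minutes: float) -> Specimen:
    """Return the specimen as it would read after a bench delay.

    For delays beyond 30 min every spectrum is shrunk toward the
    specimen's per-modality average, erasing lesion/perilesional
    contrast; the delay is recorded so QC can flag the specimen.
    """
    s = degradation_shrinkage(delay_minutes)
    if s == 0.0:
        groups = [
            SpectralGroup(
                g.point_index,
                g.site,
                tuple(Spectrum(sp.grid, sp.intensities.copy()) for sp in g.fluorescence),
                Spectrum(g.reflectance.grid, g.reflectance.intensities.copy()),
            )
            for g in specimen.groups
        ]
        return Specimen(
            specimen.specimen_id,
            specimen.truth_class,
            groups,
            specimen.fs_call,
            float(delay_minutes),
        )

    averages: dict[Modality, np.ndarray] = {}
    for modality in Modality:
        stack = [
            sp.intensities
            for g in specimen.groups
            for sp in g.spectra
            if sp.modality is modality
        ]
        averages[modality] = np.mean(stack, axis=0)

    def _shrunk(sp: Spectrum) -> Spectrum:
        mixed = (1.0 - s) * sp.intensities + s * averages[sp.modality]
        return Spectrum(sp.grid, np.clip(mixed, 0.0, None))

    groups = [
        SpectralGroup(
            g.point_index,
            g.site,
            tuple(_shrunk(sp) for sp in g.fluorescence),
            _shrunk(g.reflectance),
        )
        for g in specimen.groups
    ]
    return Specimen(
        specimen.specimen_id,
        specimen.truth_class,
        groups,
        specimen.fs_call,
        float(delay_minutes),
    )
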