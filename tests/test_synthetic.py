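"""Generator: grids, class means, sampling design, FS rater, degradation."""

import dataclasses

import numpy as np
import pytest

from specdx.data import (
    GRADED_CLASSES,
    SPECTRUM_LENGTH,
    DataModelError,
    FSCall,
    Modality,
    Site,
    SpectralClass,
    WavelengthGrid,
    cohort_summary,
)
from specdx.synthetic import (
    ConfigurationError,
    GeneratorConfig,
    class_mean_curve,
    degrade_specimen,
    fluorescence_peak_ratio,
    sample_cohort,
    sample_specimen,
    simulate_fs_call,
)


class TestWavelengthGrid:
    def test_default_grids_are_valid(self, default_config):
        for m in Modality:
            g = default_config.grid(m)
            assert len(g.points) == SPECTRUM_LENGTH
            assert np.all(np.diff(g.points) > 0)
        refl = default_config.grid(Modality.REFLECTANCE)
        assert refl.start <= 480.0 <= refl.end

    def test_reflectance_grid_must_span_480nm(self):
        with pytest.raises(DataModelError):
            WavelengthGrid(Modality.REFLECTANCE, np.linspace(500, 900, SPECTRUM_LENGTH))

    def test_non_increasing_grid_rejected(self):
        pts = np.linspace(400, 800, SPECTRUM_LENGTH)
        pts[10] = pts[9]
        with pytest.raises(DataModelError):
            WavelengthGrid(Modality.FLUORESCENCE, pts)


class TestClassMeans:
    def test_normal_vs_iac_reflectance_peaks_at_480nm(self, default_config):
        normal = class_mean_curve(default_config, SpectralClass.NORMAL, Modality.REFLECTANCE)
        iac = class_mean_curve(default_config, SpectralClass.IAC, Modality.REFLECTANCE)
        diff = np.abs(normal.intensities - iac.intensities)
        argmax_nm = normal.grid.points[int(np.argmax(diff))]
        assert argmax_nm == pytest.approx(480.0, abs=1e-9)

    def test_zero_amplitude_means_are_flat_and_class_independent(self, default_config):
        cfg = dataclasses.replace(
            default_config,
            peaks={
                m: {c: tuple((ctr, w, 0.0) for ctr, w, _a in pk)
                    for c, pk in table.items()}
                for m, table in default_config.peaks.items()
            },
        )
        curves = [
            class_mean_curve(cfg, c, Modality.REFLECTANCE).intensities
            for c in SpectralClass
        ]
        for c in curves[1:]:
            np.testing.assert_allclose(c, curves[0])

    def test_fluorescence_peak_ratio_grades_invasion(self, default_config):
        # Expected values frozen from direct evaluation of the configured
        # baseline + peak model at the 510/635 nm band centers.
        ratios = [fluorescence_peak_ratio(default_config, c) for c in GRADED_CLASSES]
        assert ratios == pytest.approx([0.281, 0.409, 0.555, 0.720], abs=5e-3)
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_inflammatory_ratio_overlaps_invasive_range(self, default_config):
        r_infl = fluorescence_peak_ratio(default_config, SpectralClass.INFLAMMATORY)
        r_mia = fluorescence_peak_ratio(default_config, SpectralClass.MIA)
        r_iac = fluorescence_peak_ratio(default_config, SpectralClass.IAC)
        assert r_mia < r_infl < r_iac

    def test_unknown_peak_table_is_configuration_error(self, default_config):
        cfg = dataclasses.replace(default_config, peaks={Modality.REFLECTANCE: {}})
        with pytest.raises(ConfigurationError):
            class_mean_curve(cfg, SpectralClass.IAC, Modality.REFLECTANCE)


class TestSampleSpecimen:
    def test_acquisition_design(self, iac_specimen):
        assert len(iac_specimen.groups) == 10
        assert len(iac_specimen.lesion_groups) == 5
        assert len(iac_specimen.perilesional_groups) == 5
        spectra = [sp for g in iac_specimen.groups for sp in g.spectra]
        assert len(spectra) == 30
        assert all(sp.intensities.shape == (SPECTRUM_LENGTH,) for sp in spectra)
        for g in iac_specimen.groups:
            assert len(g.fluorescence) == 2
            assert g.reflectance.modality is Modality.REFLECTANCE

    def test_degenerate_noise_reproduces_class_means_exactly(self, clean_config):
        specimen = sample_specimen(
            clean_config, SpectralClass.MIA, np.random.default_rng(0)
        )
        for g in specimen.lesion_groups:
            for sp in g.spectra:
                expected = class_mean_curve(clean_config, SpectralClass.MIA, sp.modality)
                np.testing.assert_array_equal(sp.intensities, expected.intensities)
        for g in specimen.perilesional_groups:
            np.testing.assert_array_equal(
                g.reflectance.intensities,
                class_mean_curve(
                    clean_config, SpectralClass.NORMAL, Modality.REFLECTANCE
                ).intensities,
            )

    def test_full_admixture_erases_lesion_contrast(self, clean_config):
        cfg = dataclasses.replace(
            clean_config, focal_mixing={c: 1.0 for c in clean_config.focal_mixing}
        )
        specimen = sample_specimen(cfg, SpectralClass.IAC, np.random.default_rng(1))
        lesion = np.mean(
            [g.reflectance.intensities for g in specimen.lesion_groups], axis=0
        )
        peri = np.mean(
            [g.reflectance.intensities for g in specimen.perilesional_groups], axis=0
        )
        np.testing.assert_allclose(lesion, peri, atol=1e-12)

    def test_normal_diagnosis_rejected(self, default_config):
        with pytest.raises(ValueError):
            sample_specimen(default_config, SpectralClass.NORMAL, np.random.default_rng(0))


class TestSampleCohort:
    @pytest.mark.parametrize("n,expected_groups", [(116, 1160), (40, 400)])
    def test_cohort_group_counts(self, default_config, n, expected_groups):
        cfg = dataclasses.replace(default_config, n_specimens=n)
        cohort = sample_cohort(cfg, seed=n)
        summary = cohort_summary(cohort)
        assert summary["n_specimens"] == n
        assert summary["n_groups"] == expected_groups
        assert summary["n_spectra"] == 3 * expected_groups

    def test_seeded_reproducibility_is_bit_identical(self, default_config):
        cfg = dataclasses.replace(default_config, n_specimens=4)
        a = sample_cohort(cfg, seed=9)
        b = sample_cohort(cfg, seed=9)
        for sa, sb in zip(a, b):
            assert sa.truth_class == sb.truth_class
            assert sa.delay_minutes == sb.delay_minutes
            for ga, gb in zip(sa.groups, sb.groups):
                for xa, xb in zip(ga.spectra, gb.spectra):
                    np.testing.assert_array_equal(xa.intensities, xb.intensities)

    def test_empty_cohort_rejected(self, default_config):
        cfg = dataclasses.replace(default_config, n_specimens=0)
        with pytest.raises(ConfigurationError):
            sample_cohort(cfg)

    def test_empty_class_mix_rejected(self, default_config):
        cfg = dataclasses.replace(default_config, class_mix={})
        with pytest.raises(ConfigurationError):
            sample_cohort(cfg)


class TestFSRater:
    def test_degenerate_probabilities(self, default_config):
        rng = np.random.default_rng(3)
        never = dataclasses.replace(
            default_config, fs_indeterminate_prob=0.0, fs_definite_error_prob=0.0
        )
        for cls in (SpectralClass.IAC, SpectralClass.MIA):
            call = simulate_fs_call(cls, never, rng)
            expected = FSCall.DEFINITE_IAC if cls.is_invasive else FSCall.DEFINITE_NON_IAC
            assert call is expected
        always = dataclasses.replace(default_config, fs_indeterminate_prob=1.0)
        assert simulate_fs_call(SpectralClass.AIS, always, rng) is FSCall.INDETERMINATE

    def test_default_rates_match_study_within_monte_carlo_error(self, default_config):
        rng = np.random.default_rng(11)
        n = 10_000
        calls = [simulate_fs_call(SpectralClass.IAC, default_config, rng) for _ in range(n)]
        p_ind = sum(c is FSCall.INDETERMINATE for c in calls) / n
        definite = [c for c in calls if c is not FSCall.INDETERMINATE]
        p_err = sum(c is FSCall.DEFINITE_NON_IAC for c in definite) / len(definite)
        se_ind = np.sqrt(0.30 * 0.70 / n)
        p0 = 1.0 / 28.0
        se_err = np.sqrt(p0 * (1 - p0) / len(definite))
        assert abs(p_ind - 0.30) < 3 * se_ind
        assert abs(p_err - p0) < 3 * se_err


def _separation(specimen) -> float:
    lesion = np.mean([g.reflectance.intensities for g in specimen.lesion_groups], axis=0)
    peri = np.mean(
        [g.reflectance.intensities for g in specimen.perilesional_groups], axis=0
    )
    return float(np.mean(np.abs(lesion - peri)))


class TestDegradation:
    def test_no_delay_is_identity_on_spectra(self, iac_specimen):
        out = degrade_specimen(iac_specimen, 0.0)
        assert out.delay_minutes == 0.0
        for ga, gb in zip(iac_specimen.groups, out.groups):
            for xa, xb in zip(ga.spectra, gb.spectra):
                np.testing.assert_array_equal(xa.intensities, xb.intensities)

    def test_long_delay_erases_class_separation(self, iac_specimen):
        before = _separation(iac_specimen)
        after = _separation(degrade_specimen(iac_specimen, 120.0))
        assert before > 0.05
        assert after < 0.05 * before

    def test_negative_delay_rejected(self, iac_specimen):
        with pytest.raises(ValueError):
            degrade_specimen(iac_specimen, -1.0)

    def test_monotone_contrast_loss(self, iac_specimen):
        seps = [
            _separation(degrade_specimen(iac_specimen, d)) for d in (0, 31, 45, 60, 120)
        ]
        assert all(a >= b for a, b in zip(seps, seps[1:]))
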