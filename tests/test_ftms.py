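"""FTMS peak picking, assignment, natural-abundance correction, quantification."""

import dataclasses

import numpy as np
import pytest

from glycotrace.ftms import (
    AmbiguousSpeciesError,
    Peak,
    SpikeCollisionError,
    assign_peaks,
    build_correction_matrix,
    correct_natural_abundance,
    matched_filter_area,
    pick_peaks,
    quantify_spectrum,
    quantify_with_standard,
)
from glycotrace.isotopes import (
    FineStructure,
    FineStructureLine,
    IsotopologueSpecies,
    enumerate_species,
    natural_abundance_fine_structure,
)
from glycotrace.spectra import Spectrum
from glycotrace.synth import SpectrumSynthConfig, synthesize_ftms_spectrum

M0 = IsotopologueSpecies()
SPIKE_13C6 = IsotopologueSpecies(n13C=6)
SPIKE_DUAL = IsotopologueSpecies(n13C=6, n2H=7)


def delta_fine_structure(species):
    """Degenerate fine structure: all probability on the species' own mass."""
    return FineStructure(
        species=species,
        lines=(FineStructureLine((), species.exact_mass, 1.0),),
        dropped_probability=0.0,
        renormalized=False,
    )


class TestPickPeaks:
    def test_noiseless_gaussian_centroids_to_center(self, noiseless_config):
        spectrum = synthesize_ftms_spectrum({M0: 10.0}, None, noiseless_config)
        peaks = pick_peaks(spectrum)
        principal = max(peaks, key=lambda p: p.intensity)
        assert principal.mz == pytest.approx(M0.exact_mass, abs=1e-4)

    def test_flat_zero_spectrum_has_no_peaks(self):
        spectrum = Spectrum(np.linspace(100, 110, 500), np.zeros(500))
        assert pick_peaks(spectrum) == []

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            pick_peaks(Spectrum(np.array([]), np.array([])))

    def test_two_resolvable_species_give_two_principal_peaks(self):
        cfg = SpectrumSynthConfig(seed=3, probability_floor=0.5)
        spectrum = synthesize_ftms_spectrum(
            {IsotopologueSpecies(n13C=1): 10.0, IsotopologueSpecies(n2H=1): 10.0},
            None,
            cfg,
        )
        peaks = pick_peaks(spectrum, snr_threshold=5.0)
        tall = [p for p in peaks if p.intensity > 0.5 * max(q.intensity for q in peaks)]
        assert len(tall) == 2


class TestAssignPeaks:
    def test_exact_mass_assigns_at_zero_ppm(self):
        species = enumerate_species({"13C"})
        peaks = [Peak(mz=M0.exact_mass, intensity=1.0)]
        (assignment,) = assign_peaks(peaks, species)
        assert assignment.species == M0
        assert assignment.mass_error_ppm == pytest.approx(0.0, abs=1e-6)

    def test_far_peak_stays_unassigned(self):
        species = enumerate_species({"13C"})
        peaks = [Peak(mz=M0.exact_mass + 0.5, intensity=1.0)]
        (assignment,) = assign_peaks(peaks, species)
        assert assignment.species is None

    def test_near_isobars_resolve_to_distinct_species(self):
        species = [IsotopologueSpecies(n13C=1), IsotopologueSpecies(n2H=1)]
        peaks = [Peak(sp.exact_mass, 1.0) for sp in species]
        assignments = assign_peaks(peaks, species, tolerance_ppm=5.0)
        assert [a.species for a in assignments] == species

    def test_species_clash_within_tolerance_is_ambiguous(self):
        species = [IsotopologueSpecies(n13C=1), IsotopologueSpecies(n2H=1)]
        with pytest.raises(AmbiguousSpeciesError, match="13C1"):
            assign_peaks([Peak(182.0, 1.0)], species, tolerance_ppm=50.0)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            assign_peaks([], [M0], tolerance_ppm=0.0)


class TestNaturalAbundanceCorrection:
    def test_identity_fine_structure_returns_input(self):
        species = enumerate_species({"13C"})
        observed = np.linspace(1.0, 7.0, len(species))
        corrected = correct_natural_abundance(
            observed, species, [delta_fine_structure(sp) for sp in species]
        )
        np.testing.assert_allclose(corrected, observed)

    def test_pure_unlabeled_concentrates_at_monoisotopic_channel(self):
        species = enumerate_species({"13C"})
        C = build_correction_matrix(species)
        observed = C @ np.array([100.0, 0, 0, 0, 0, 0, 0])
        corrected = correct_natural_abundance(observed, species)
        assert corrected[0] / corrected.sum() > 0.99

    def test_fifty_fifty_mixture_roundtrip(self):
        species = enumerate_species({"13C"})
        truth = np.array([50.0, 0, 0, 0, 0, 0, 50.0])
        C = build_correction_matrix(species)
        corrected = correct_natural_abundance(C @ truth, species)
        fractions = corrected / corrected.sum()
        assert fractions[0] == pytest.approx(0.5, abs=0.005)
        assert fractions[-1] == pytest.approx(0.5, abs=0.005)

    def test_columns_sum_to_at_most_one(self):
        for tracers in ({"13C"}, {"2H"}, {"13C", "2H"}):
            species = enumerate_species(tracers)
            C = build_correction_matrix(species, resolving_power=500_000)
            sums = C.sum(axis=0)
            assert np.all(sums <= 1.0 + 1e-9)
            assert np.all(sums > 0.85)  # most probability lands on-channel

    def test_clipping_warns_above_threshold(self):
        species = enumerate_species({"13C"})
        observed = np.zeros(7)
        observed[1] = -50.0
        observed[0] = 100.0
        with pytest.warns(UserWarning, match="clipped"):
            correct_natural_abundance(
                observed, species, [delta_fine_structure(sp) for sp in species]
            )

    def test_singular_matrix_rejected(self):
        species = enumerate_species({"13C"})[:2]
        degenerate = [delta_fine_structure(species[0])] * 2
        with pytest.raises(ValueError, match="ill-conditioned"):
            correct_natural_abundance(np.ones(2), species, degenerate)


class TestQuantifyWithStandard:
    def test_amounts_proportional_to_spike(self):
        species = [M0, SPIKE_13C6]
        result = quantify_with_standard(
            np.array([2.0, 1.0]), species, SPIKE_13C6, 10.0
        )
        assert result.total_nmol == pytest.approx(20.0)

    def test_zero_analyte_quantifies_to_zero(self):
        species = [M0, SPIKE_13C6]
        result = quantify_with_standard(
            np.array([0.0, 1.0]), species, SPIKE_13C6, 10.0
        )
        assert result.total_nmol == 0.0

    def test_spike_channel_excluded_from_fractions(self):
        species = [M0, SPIKE_13C6]
        result = quantify_with_standard(
            np.array([2.0, 1.0]), species, SPIKE_13C6, 10.0
        )
        assert SPIKE_13C6 not in result.species
        assert result.fractions.sum() == pytest.approx(1.0)

    def test_spike_colliding_with_analyte_is_rejected(self):
        species = enumerate_species({"13C"})
        with pytest.raises(SpikeCollisionError, match="dual-labeled"):
            quantify_with_standard(
                np.ones(len(species)),
                species,
                SPIKE_13C6,
                10.0,
                analyte_species=species,
            )

    def test_nonpositive_spike_rejected(self):
        with pytest.raises(ValueError):
            quantify_with_standard(np.array([1.0, 1.0]), [M0, SPIKE_13C6], SPIKE_13C6, 0.0)


class TestQuantifySpectrum:
    def test_noiseless_end_to_end_recovers_amounts(self, noiseless_config):
        species = enumerate_species({"13C"})
        amounts = {species[0]: 40.0, species[3]: 15.0, species[6]: 30.0}
        spectrum = synthesize_ftms_spectrum(amounts, (SPIKE_DUAL, 50.0), noiseless_config)
        result = quantify_spectrum(
            spectrum, species, SPIKE_DUAL, 50.0,
            resolving_power=noiseless_config.resolving_power,
        )
        assert result.total_nmol == pytest.approx(85.0, rel=0.01)
        assert result.amount_of("13C3") == pytest.approx(15.0, rel=0.02)

    def test_invariant_to_uniform_intensity_scaling(self, synth_config):
        species = enumerate_species({"13C"})
        amounts = {species[0]: 40.0, species[6]: 30.0}
        spectrum = synthesize_ftms_spectrum(amounts, (SPIKE_DUAL, 50.0), synth_config)
        scaled = Spectrum(spectrum.axis.copy(), spectrum.intensity * 37.0)
        a = quantify_spectrum(
            spectrum, species, SPIKE_DUAL, 50.0,
            resolving_power=synth_config.resolving_power,
        )
        b = quantify_spectrum(
            scaled, species, SPIKE_DUAL, 50.0,
            resolving_power=synth_config.resolving_power,
        )
        np.testing.assert_allclose(a.amounts_nmol, b.amounts_nmol, rtol=1e-9)

    def test_spike_in_analyte_ladder_rejected(self, synth_config):
        species = enumerate_species({"13C"})
        with pytest.raises(SpikeCollisionError):
            quantify_spectrum(
                Spectrum(np.linspace(180, 200, 100), np.zeros(100)),
                species,
                SPIKE_13C6,
                10.0,
                resolving_power=500_000,
            )

    def test_matched_filter_recovers_known_area(self):
        mz0, sigma = 181.0707, 1.5e-4
        axis = np.arange(mz0 - 30 * sigma, mz0 + 30 * sigma, sigma / 10)
        area = 250.0
        y = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((axis - mz0) / sigma) ** 2
        )
        spectrum = Spectrum(axis, y)
        # resolving power implying this sigma: fwhm = 2.3548 sigma
        resolving_power = mz0 / (2.3548 * sigma) / np.sqrt(200.0 / mz0)
        est = matched_filter_area(spectrum, mz0, resolving_power)
        assert est == pytest.approx(area, rel=1e-3)
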