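"""Synthetic-data generator: labeling, hydrolysis kinetics, spectra."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycotrace.isotopes import IsotopologueSpecies
from glycotrace.synth import (
    DEFAULT_HYDROLYSIS_MODEL,
    FTMS_AREA_PER_NMOL,
    GLUCOSE_PER_GLYCOGEN_NMOL_PER_UG,
    HydrolysisModel,
    LabelingScenario,
    SpectrumSynthConfig,
    simulate_hydrolysis,
    simulate_labeling,
    synthesize_ftms_spectrum,
    synthesize_nmr_spectrum,
)


def brute_force_scramble_pmf(n_positions: int, p: float) -> np.ndarray:
    """Oracle: enumerate all 2^n retention patterns explicitly."""
    pmf = np.zeros(n_positions + 1)
    for pattern in itertools.product([0, 1], repeat=n_positions):
        k = sum(pattern)
        prob = np.prod([p if kept else 1 - p for kept in pattern])
        pmf[k] += prob
    return pmf


class TestSimulateLabeling:
    def test_pure_direct_incorporation(self):
        species, fracs = simulate_labeling(
            LabelingScenario(f_unlabeled=0.0, f_direct=1.0, tracer="13C6")
        )
        assert fracs[-1] == pytest.approx(1.0)
        assert species[-1].n13C == 6

    def test_liver_like_two_component_split(self):
        # 55.1% unlabeled / 44.9% fully labeled mimics the in vivo liver split
        _, fracs = simulate_labeling(
            LabelingScenario(f_unlabeled=0.551, f_direct=0.449, tracer="13C6")
        )
        assert fracs[0] == pytest.approx(0.551)
        assert fracs[-1] == pytest.approx(0.449)
        assert fracs[1:-1].sum() == pytest.approx(0.0)

    def test_scrambling_matches_bruteforce_enumeration(self):
        _, fracs = simulate_labeling(
            LabelingScenario(
                f_unlabeled=0.0,
                f_direct=0.0,
                f_scrambled=1.0,
                scramble_retention=0.5,
                tracer="13C6",
            )
        )
        oracle = brute_force_scramble_pmf(6, 0.5)
        np.testing.assert_allclose(fracs, oracle, atol=1e-12)
        assert fracs[3] == pytest.approx(0.3125)

    def test_deuterium_ladder_has_eight_rungs(self):
        species, fracs = simulate_labeling(
            LabelingScenario(
                f_unlabeled=0.5, f_direct=0.3, f_scrambled=0.2, tracer="2H7"
            )
        )
        assert len(species) == 8
        assert fracs.sum() == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        f_direct=st.floats(0.0, 1.0),
        f_scrambled=st.floats(0.0, 1.0),
        p=st.floats(0.0, 1.0),
    )
    def test_fractions_always_sum_to_one(self, f_direct, f_scrambled, p):
        total_labeled = f_direct + f_scrambled
        if total_labeled > 1.0:
            f_direct /= total_labeled
            f_scrambled /= total_labeled
        scenario = LabelingScenario(
            f_unlabeled=max(1.0 - f_direct - f_scrambled, 0.0),
            f_direct=f_direct,
            f_scrambled=f_scrambled,
            scramble_retention=p,
            tracer="2H7",
        )
        _, fracs = simulate_labeling(scenario)
        assert fracs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(fracs >= 0)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            LabelingScenario(f_unlabeled=0.6, f_direct=0.6)
        with pytest.raises(ValueError):
            LabelingScenario(f_unlabeled=1.0, f_direct=0.0, scramble_retention=1.5)


class TestHydrolysisModel:
    def test_optimal_condition_recovers_over_ninety_percent(self):
        out = simulate_hydrolysis(100.0, 110.0, 10.0)
        assert out["recovery_fraction"] > 0.90

    def test_suboptimal_temperature_still_recovers_most(self):
        out = simulate_hydrolysis(100.0, 105.0, 10.0)
        assert out["recovery_fraction"] >= 0.71

    def test_overlong_incubation_degrades_glucose(self):
        r10 = simulate_hydrolysis(100.0, 110.0, 10.0)
        r30 = simulate_hydrolysis(100.0, 110.0, 30.0)
        assert r30["recovery_fraction"] < r10["recovery_fraction"]
        assert r30["hmf_nmol"] > r10["hmf_nmol"]

    def test_recovery_unimodal_in_temperature(self):
        temps = np.arange(20.0, 201.0, 5.0)
        recoveries = [
            simulate_hydrolysis(1.0, t, 10.0)["recovery_fraction"] for t in temps
        ]
        peak = int(np.argmax(recoveries))
        assert all(np.diff(recoveries[: peak + 1]) >= -1e-12)
        assert all(np.diff(recoveries[peak:]) <= 1e-12)
        # the optimum sits in the experimentally observed plateau
        assert 105.0 <= temps[peak] <= 115.0

    def test_no_degradation_limit_reaches_complete_recovery(self):
        model = HydrolysisModel.from_reference_rates(
            k_hyd_ref=0.45, k_deg_ref=0.0, Ea_hyd=248e3, Ea_deg=200e3
        )
        out = simulate_hydrolysis(100.0, 110.0, 1e4, model)
        assert out["recovery_fraction"] == pytest.approx(1.0, abs=1e-9)

    def test_glucose_yield_uses_residue_equivalent(self):
        out = simulate_hydrolysis(10.0, 110.0, 10.0)
        expected = out["recovery_fraction"] * 10.0 * GLUCOSE_PER_GLYCOGEN_NMOL_PER_UG
        assert out["glucose_nmol"] == pytest.approx(expected)

    def test_zero_time_zero_recovery(self):
        assert simulate_hydrolysis(10.0, 110.0, 0.0)["recovery_fraction"] == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"glycogen_ug": -1.0, "temperature_C": 110.0, "time_min": 10.0},
            {"glycogen_ug": 1.0, "temperature_C": 10.0, "time_min": 10.0},
            {"glycogen_ug": 1.0, "temperature_C": 110.0, "time_min": -1.0},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_hydrolysis(**kwargs)

    def test_mass_balance_never_exceeds_input(self):
        for t in (1.0, 5.0, 15.0, 60.0):
            out = simulate_hydrolysis(1.0, 120.0, t)
            total = out["glucose_nmol"] + out["hmf_nmol"]
            assert total <= 1.0 * GLUCOSE_PER_GLYCOGEN_NMOL_PER_UG + 1e-9


class TestFTMSSynthesis:
    def test_single_species_peak_at_expected_mass(self, noiseless_config):
        sp = IsotopologueSpecies()
        spectrum = synthesize_ftms_spectrum({sp: 10.0}, None, noiseless_config)
        apex = spectrum.axis[np.argmax(spectrum.intensity)]
        assert apex == pytest.approx(181.0707, abs=1e-4)

    def test_zero_amounts_gives_noise_only_spectrum(self, synth_config):
        spectrum = synthesize_ftms_spectrum({}, None, synth_config)
        assert len(spectrum) > 0
        assert np.abs(spectrum.intensity).max() < 6 * synth_config.noise_sd

    def test_total_area_linear_in_amount(self, noiseless_config):
        sp = IsotopologueSpecies()
        areas = []
        for nmol in (1.0, 2.0, 4.0):
            spectrum = synthesize_ftms_spectrum({sp: nmol}, None, noiseless_config)
            areas.append(np.trapezoid(spectrum.intensity, spectrum.axis))
        assert areas[1] / areas[0] == pytest.approx(2.0, rel=1e-3)
        assert areas[2] / areas[0] == pytest.approx(4.0, rel=1e-3)
        assert areas[0] == pytest.approx(FTMS_AREA_PER_NMOL, rel=0.08)

    def test_near_isobars_split_at_high_not_low_resolving_power(self):
        pair = {
            IsotopologueSpecies(n13C=1): 10.0,
            IsotopologueSpecies(n2H=1): 10.0,
        }

        def count_maxima(resolving_power):
            cfg = SpectrumSynthConfig(
                seed=0,
                noise_sd=0.0,
                resolving_power=resolving_power,
                probability_floor=0.5,  # suppress natural-abundance side lines
            )
            spectrum = synthesize_ftms_spectrum(pair, None, cfg)
            y = spectrum.intensity
            interior = np.arange(1, y.size - 1)
            is_max = (y[interior] > y[interior - 1]) & (y[interior] >= y[interior + 1])
            return int(np.sum(is_max & (y[interior] > 0.1 * y.max())))

        assert count_maxima(500_000) == 2
        assert count_maxima(10_000) == 1

    def test_unresolvable_spike_rejected(self, synth_config):
        analyte = IsotopologueSpecies(n13C=1)
        near_isobar_spike = IsotopologueSpecies(n2H=1)
        cfg = dataclasses.replace(synth_config, resolving_power=10_000)
        with pytest.raises(ValueError, match="not resolvable"):
            synthesize_ftms_spectrum({analyte: 5.0}, (near_isobar_spike, 5.0), cfg)

    def test_missing_seed_is_an_error(self):
        cfg = SpectrumSynthConfig(seed=None)
        with pytest.raises(ValueError, match="seed"):
            synthesize_ftms_spectrum({IsotopologueSpecies(): 1.0}, None, cfg)

    def test_fixed_seed_is_bit_reproducible(self, synth_config):
        args = ({IsotopologueSpecies(): 5.0}, (IsotopologueSpecies(n13C=6), 10.0))
        a = synthesize_ftms_spectrum(*args, synth_config)
        b = synthesize_ftms_spectrum(*args, synth_config)
        assert np.array_equal(a.axis, b.axis)
        assert np.array_equal(a.intensity, b.intensity)
        assert a.metadata["seed"] == synth_config.seed


class TestNMRSynthesis:
    def test_no_enrichment_no_satellites(self, noiseless_config):
        from glycotrace.nmr import DEFAULT_WINDOWS, integrate_pool

        spectrum = synthesize_nmr_spectrum(
            {"glycogen": {"conc_mM": 2.0, "F": 0.0}}, 0.5, noiseless_config
        )
        integrals = integrate_pool(spectrum, DEFAULT_WINDOWS, "glycogen_H1a")
        assert integrals.I_13C < 0.01 * integrals.I_12C

    def test_satellite_share_equals_enrichment_on_noiseless_spectrum(
        self, noiseless_config
    ):
        from glycotrace.nmr import DEFAULT_WINDOWS, fraction_13C, integrate_pool

        spectrum = synthesize_nmr_spectrum(
            {"glycogen": {"conc_mM": 2.0, "F": 0.63}}, 0.5, noiseless_config
        )
        integrals = integrate_pool(spectrum, DEFAULT_WINDOWS, "glycogen_H1a")
        assert fraction_13C(integrals) == pytest.approx(0.63, abs=0.005)

    def test_equilibrium_anomer_ratio(self, noiseless_config):
        from glycotrace.nmr import DEFAULT_WINDOWS, integrate_pool

        spectrum = synthesize_nmr_spectrum(
            {"glucose": {"conc_mM": 1.0, "F": 0.0}}, 0.5, noiseless_config
        )
        alpha = integrate_pool(spectrum, DEFAULT_WINDOWS, "glucose_H1a")
        beta = integrate_pool(spectrum, DEFAULT_WINDOWS, "glucose_H1b")
        ratio = (alpha.I_12C + alpha.I_13C) / (beta.I_12C + beta.I_13C)
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_enrichment_out_of_range_rejected(self, synth_config):
        with pytest.raises(ValueError):
            synthesize_nmr_spectrum(
                {"glycogen": {"conc_mM": 1.0, "F": 1.2}}, 0.5, synth_config
            )

    def test_fixed_seed_is_bit_reproducible(self, synth_config):
        pools = {"glucose": {"conc_mM": 1.0, "F": 0.5}}
        a = synthesize_nmr_spectrum(pools, 0.5, synth_config)
        b = synthesize_nmr_spectrum(pools, 0.5, synth_config)
        assert np.array_equal(a.intensity, b.intensity)
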