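import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import ctdinuc as cd
from ctdinuc.constants import NM_EV, ev_to_nm, nm_to_ev
from ctdinuc.electronic_structure import EsaLine, Transition, osc_strength_from_dipole
from ctdinuc.spectra import SpectralGrid, Spectrum, scaled_to_peak

FINE = SpectralGrid(np.arange(250.0, 450.0, 0.05))
PEAK_PER_EV = 1.0 / (0.4 / math.sqrt(8 * math.log(2)) * math.sqrt(2 * math.pi))  # 2.3485


class TestBroaden:
    def test_unshifted_stick_peak_position_and_height(self):
        spec = cd.broaden([(4.0, 1.0)], cd.BroadeningConfig(shift_ev=0.0), FINE)
        wl, height = spec.peak()
        assert wl == pytest.approx(NM_EV / 4.0, abs=0.05)
        assert height == pytest.approx(PEAK_PER_EV, rel=1e-3)

    def test_calibration_shift_moves_peak(self):
        spec = cd.broaden([(4.0, 1.0)], cd.BroadeningConfig(shift_ev=-0.65), FINE)
        wl, _ = spec.peak()
        assert wl == pytest.approx(NM_EV / 3.35, abs=0.05)

    def test_zero_weight_gives_zero_spectrum(self):
        spec = cd.broaden([(4.0, 0.0)], grid=FINE)
        assert np.all(spec.values == 0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cd.BroadeningConfig(fwhm_ev=0.0)
        with pytest.raises(ValueError):
            cd.broaden([], grid=FINE)

    def test_area_conservation_against_quadrature(self):
        cfg = cd.BroadeningConfig(shift_ev=0.0)
        weight = 0.37
        spec = cd.broaden([(4.0, weight)], cfg, FINE)  # band well inside the grid
        e = FINE.energies_ev
        sampled_area = -np.trapezoid(spec.values, e)  # energy decreases along the grid
        sigma = cfg.sigma_ev
        oracle, _ = quad(
            lambda x: weight * math.exp(-0.5 * ((x - 4.0) / sigma) ** 2)
            / (sigma * math.sqrt(2 * math.pi)),
            e.min(), e.max(),
        )
        assert sampled_area == pytest.approx(oracle, rel=1e-6)
        assert sampled_area == pytest.approx(weight, rel=1e-6)

    def test_nm_ev_conversion_is_an_involution(self):
        wl = np.linspace(200.0, 650.0, 31)
        assert np.allclose(ev_to_nm(nm_to_ev(wl)), wl, rtol=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        energies=st.lists(st.floats(3.8, 5.5), min_size=1, max_size=5),
        scale=st.floats(0.1, 10.0),
    )
    def test_linear_in_stick_weights(self, energies, scale):
        sticks = [(e, 0.1 + 0.05 * i) for i, e in enumerate(energies)]
        scaled = [(e, scale * w) for e, w in sticks]
        base = cd.broaden(sticks, grid=FINE).values
        assert np.allclose(cd.broaden(scaled, grid=FINE).values, scale * base, rtol=1e-12)


class TestSteadyStateSpectra:
    def test_absorption_is_sum_of_individual_transitions(self, ga_model, cfg, steady):
        total = cd.absorption_spectrum(ga_model, cfg, steady).values
        parts = sum(
            cd.broaden([(t.energy_ev, t.osc_strength)], cfg, steady).values
            for t in ga_model.transitions
        )
        assert np.allclose(total, parts, rtol=1e-12)

    def test_ag_conformers_peak_blue_of_ga_and_stronger(
        self, ag_model, ag_anti_anti_model, ga_model, cfg, steady
    ):
        ga_wl, ga_max = cd.absorption_spectrum(ga_model, cfg, steady).peak()
        for model in (ag_model, ag_anti_anti_model):
            ag_wl, ag_max = cd.absorption_spectrum(model, cfg, steady).peak()
            assert ag_wl < ga_wl
            assert ag_max > ga_max

    def test_cd_zero_rotatory_strengths_give_zero(self, cfg, steady):
        model = cd.ConformerModel(
            name="anti-anti", dinucleotide="GA", delta_g_ev=0.0,
            transitions=(Transition("S1", 5.0, 0.1, rotatory_strength=0.0),),
        )
        assert np.all(cd.cd_spectrum(model, cfg, steady).values == 0.0)

    def test_cd_negation_flips_spectrum(self, ga_model, cfg, steady):
        flipped = cd.ConformerModel(
            name=ga_model.name, dinucleotide=ga_model.dinucleotide,
            delta_g_ev=ga_model.delta_g_ev,
            transitions=tuple(
                Transition(t.label, t.energy_ev, t.osc_strength, -t.rotatory_strength,
                           t.ct_character_au, t.character, "none")
                for t in ga_model.transitions
            ),
        )
        assert np.allclose(
            cd.cd_spectrum(flipped, cfg, steady).values,
            -cd.cd_spectrum(ga_model, cfg, steady).values,
            rtol=1e-12,
        )

    def test_ga_cd_negative_then_positive_from_long_wavelengths(self, ga_model, cfg, steady):
        values = cd.cd_spectrum(ga_model, cfg, steady).values
        threshold = 0.01 * np.max(np.abs(values))
        signs = []
        for v in values[::-1]:  # long -> short wavelength
            s = int(np.sign(v)) if abs(v) > threshold else 0
            if s and (not signs or s != signs[-1]):
                signs.append(s)
        assert signs[:2] == [-1, 1]


class TestEsaSpectra:
    def test_single_line_area_equals_oscillator_strength(self, cfg):
        grid = SpectralGrid(np.arange(260.0, 650.0, 0.1))
        line = EsaLine("min-CT", 3.0 + 0.65, 1.0)  # shifted center at 3.0 eV
        spec = cd.esa_spectrum([line], cfg, grid)
        area = -np.trapezoid(spec.values, grid.energies_ev)
        assert area == pytest.approx(osc_strength_from_dipole(3.65, 1.0), rel=1e-5)

    def test_empty_line_list_is_zero_not_error(self, cfg, probe):
        spec = cd.esa_spectrum([], cfg, probe)
        assert np.all(spec.values == 0.0)

    def test_doubling_dipoles_doubles_spectrum(self, ga_model, cfg, probe):
        lines = ga_model.esa_for("min-CT")
        doubled = [EsaLine(l.from_state, l.delta_e_ev, 2 * l.dipole_sq_au) for l in lines]
        assert np.allclose(
            cd.esa_spectrum(doubled, cfg, probe).values,
            2 * cd.esa_spectrum(lines, cfg, probe).values,
            rtol=1e-12,
        )

    def test_ga_ct_minimum_blue_shifted_and_stronger_than_its_fc_state(
        self, ga_model, cfg, probe
    ):
        fc = cd.esa_spectrum(ga_model.esa_for("S2"), cfg, probe)
        minimum = cd.esa_spectrum(ga_model.esa_for("min-CT"), cfg, probe)
        fc_wl, fc_max = fc.peak((450.0, 650.0))
        min_wl, min_max = minimum.peak((450.0, 650.0))
        assert min_wl < fc_wl
        assert min_max > fc_max


class TestPumpWeighting:
    def _model(self, energy_ev, f):
        return cd.ConformerModel(
            name="anti-anti", dinucleotide="GA", delta_g_ev=0.0,
            transitions=(Transition("S1", energy_ev, f),),
        )

    def test_dark_state_gets_zero_weight(self, cfg):
        w = cd.fc_weights_at_pump(self._model(5.5, 0.0), cfg, 266.0)
        assert w["S1"] == 0.0

    def test_resonant_state_weight_is_gaussian_peak_times_f(self, cfg):
        resonant = nm_to_ev(266.0) + 0.65  # shifted band centred exactly on the pump
        w = cd.fc_weights_at_pump(self._model(resonant, 0.2), cfg, 266.0)
        assert w["S1"] == pytest.approx(0.2 * PEAK_PER_EV, rel=1e-3)

    def test_weights_scale_linearly_with_f(self, cfg):
        w1 = cd.fc_weights_at_pump(self._model(5.5, 0.1), cfg, 266.0)["S1"]
        w3 = cd.fc_weights_at_pump(self._model(5.5, 0.3), cfg, 266.0)["S1"]
        assert w3 == pytest.approx(3 * w1, rel=1e-12)

    def test_single_fc_state_superposition_is_weight_times_esa(self, ag_model, cfg, probe):
        first = ag_model.transitions[0]
        lone = cd.ConformerModel(
            name="anti-syn", dinucleotide="AG", delta_g_ev=0.0,
            transitions=(Transition("S1", first.energy_ev, first.osc_strength),),
            esa_lines=tuple(
                EsaLine("S1", l.delta_e_ev, l.dipole_sq_au)
                for l in ag_model.esa_for("S1")
            ),
        )
        weight = cd.fc_weights_at_pump(lone, cfg, 266.0)["S1"]
        combo = cd.weighted_fc_tas(lone, cfg, 266.0, probe)
        esa = cd.esa_spectrum(lone.esa_for("S1"), cfg, probe)
        assert np.allclose(combo.values, weight * esa.values, rtol=1e-12)

    def test_ga_combination_stronger_than_ag_at_band_edges(self, ga_model, ag_model, cfg, probe):
        ga = cd.weighted_fc_tas(ga_model, cfg, 266.0, probe).values
        ag = cd.weighted_fc_tas(ag_model, cfg, 266.0, probe).values
        wl = probe.wavelengths_nm
        low_energy = wl >= 600.0
        high_energy = wl <= 380.0
        assert ga[low_energy].mean() > ag[low_energy].mean()
        assert ga[high_energy].mean() > ag[high_energy].mean()

    def test_dark_model_combination_is_zero(self, cfg, probe):
        model = cd.ConformerModel(
            name="anti-anti", dinucleotide="GA", delta_g_ev=0.0,
            transitions=(Transition("S1", 5.5, 0.0),),
            esa_lines=(EsaLine("S1", 3.0, 1.0),),
        )
        assert np.all(cd.weighted_fc_tas(model, cfg, 266.0, probe).values == 0.0)


class TestThermalDifference:
    def _flat(self, grid, value=1.0):
        return Spectrum(grid, np.full(len(grid), value))

    def test_identical_spectra_give_zero(self, steady):
        spec = self._flat(steady)
        diff, percent = cd.thermal_difference(spec, spec)
        assert np.all(diff.values == 0.0)
        assert percent == 0.0

    def test_uniform_ratio_recovers_plateau_percent(self, steady):
        cold = self._flat(steady)
        hot = Spectrum(steady, 1.037 * cold.values)
        _, percent = cd.thermal_difference(hot, cold)
        assert percent == pytest.approx(3.7, abs=1e-9)

    def test_first_order_antisymmetry_under_swap(self, steady):
        cold = self._flat(steady, 1.0)
        hot = Spectrum(steady, 1.001 * cold.values)
        d1, _ = cd.thermal_difference(hot, cold)
        d2, _ = cd.thermal_difference(cold, hot)
        assert np.allclose(d1.values, -d2.values, atol=1e-5)

    def test_grid_mismatch_rejected(self, steady, probe):
        with pytest.raises(ValueError, match="grid"):
            cd.thermal_difference(self._flat(steady), self._flat(probe))

    def test_zero_cold_points_excluded_with_warning(self, steady):
        cold_values = np.ones(len(steady))
        cold_values[0] = 0.0
        cold = Spectrum(steady, cold_values)
        hot = Spectrum(steady, 1.02 * np.ones(len(steady)))
        with pytest.warns(UserWarning, match="excluded"):
            _, percent = cd.thermal_difference(hot, cold)
        assert percent == pytest.approx(2.0, abs=1e-9)


def test_scaled_to_peak_sets_band_maximum(ga_model, cfg, probe):
    spec = cd.esa_spectrum(ga_model.esa_for("min-CT"), cfg, probe)
    scaled = scaled_to_peak(spec, 1230.0, band_nm=(500.0, 645.0))
    _, peak = scaled.peak((500.0, 645.0))
    assert peak == pytest.approx(1230.0, rel=1e-12)
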