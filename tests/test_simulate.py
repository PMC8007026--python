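"""Synthetic spectrum generator: line rules, determinism, ground-truth areas."""

import math

import numpy as np
import pytest

import nmrmetab as nm
from nmrmetab.library import MultipletSignal, parse_multiplet_string
from nmrmetab.simulate import multiplet_lines

from conftest import window_mask


class TestMultipletLines:
    def test_doublet_spacing_is_j_over_field(self):
        sig = MultipletSignal(1.33, "d", (7.0,))
        lines = multiplet_lines(sig, 400.0)
        assert lines == [(-0.00875, 0.5), (0.00875, 0.5)]

    def test_singlet(self):
        assert multiplet_lines(MultipletSignal(2.0, "s"), 400.0) == [(0.0, 1.0)]

    def test_triplet_binomial(self):
        lines = multiplet_lines(MultipletSignal(2.0, "t", (7.0,)), 400.0)
        assert [w for _, w in lines] == [0.25, 0.5, 0.25]
        assert lines[2][0] == pytest.approx(7.0 / 400.0)

    def test_quartet_binomial(self):
        lines = multiplet_lines(MultipletSignal(4.11, "q", (7.0,)), 400.0)
        assert [w for _, w in lines] == [1 / 8, 3 / 8, 3 / 8, 1 / 8]

    def test_dd_four_equal_lines(self):
        lines = multiplet_lines(MultipletSignal(2.5, "dd", (4.0, 10.0)), 400.0)
        assert [w for _, w in lines] == [0.25] * 4
        assert lines[0][0] == pytest.approx(-(4 + 10) / 2 / 400)

    @pytest.mark.parametrize("code", ["s", "d", "t", "q", "dd", "m"])
    def test_intensities_normalized_and_symmetric(self, code):
        sig = parse_multiplet_string(f"2.0({code})")[0]
        lines = multiplet_lines(sig, 400.0)
        assert sum(w for _, w in lines) == pytest.approx(1.0)
        offs = [o for o, _ in lines]
        assert offs == pytest.approx([-o for o in reversed(offs)])

    def test_bad_field_rejected(self):
        with pytest.raises(ValueError):
            multiplet_lines(MultipletSignal(1.0, "s"), 0.0)

    def test_unknown_code_rejected_at_construction(self):
        with pytest.raises(Exception):
            MultipletSignal(1.0, "xx")


class TestSimulateSpectrumSet:
    def test_no_stochastic_terms_gives_identical_samples(
        self, clean_design, intracellular_library
    ):
        sset = nm.simulate_spectrum_set(clean_design, intracellular_library, n_points=4096)
        for i in range(1, sset.n_samples):
            np.testing.assert_array_equal(sset.data[0], sset.data[i])

    def test_same_seed_bitwise_identical(self, intracellular_library, small_panel):
        design = nm.StudyDesign(base_concentrations=small_panel, seed=3)
        a = nm.simulate_spectrum_set(design, intracellular_library, n_points=4096)
        b = nm.simulate_spectrum_set(design, intracellular_library, n_points=4096)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.truth == b.truth

    def test_adding_samples_preserves_earlier_ones(
        self, intracellular_library, small_panel
    ):
        d5 = nm.StudyDesign(base_concentrations=small_panel, n_control=2,
                            n_knockdown=2, seed=3)
        d6 = nm.StudyDesign(base_concentrations=small_panel, n_control=2,
                            n_knockdown=3, seed=3)
        a = nm.simulate_spectrum_set(d5, intracellular_library, n_points=4096)
        b = nm.simulate_spectrum_set(d6, intracellular_library, n_points=4096)
        np.testing.assert_array_equal(a.data, b.data[: a.n_samples])

    def test_noiseless_area_matches_concentration(self, intracellular_library):
        conc = 2.5
        design = nm.StudyDesign(
            n_control=2, n_knockdown=2,
            base_concentrations={"Formate": conc}, log2_effects={},
            biological_cv=0.0, dilution_range=(1, 1), noise_sd=0.0,
            phase0_range=0.0, phase1_range=0.0, baseline_amplitude=0.0,
            shift_jitter_sd=0.0, seed=0,
        )
        sset = nm.simulate_spectrum_set(
            design, intracellular_library, n_points=32768, water_height=0.0
        )
        # formate: one singlet at 8.46 ppm; integrate over ~150 half-widths
        # (narrower windows lose >1% to Lorentzian tails)
        mask = window_mask(sset.ppm, [(8.0, 8.92)])
        area = np.trapezoid(sset.data[0].real[mask], sset.ppm[mask])
        assert area == pytest.approx(conc, rel=0.01)

    def test_linearity_in_concentration(self, intracellular_library):
        kw = dict(
            n_control=2, n_knockdown=2, log2_effects={}, biological_cv=0.0,
            dilution_range=(1, 1), noise_sd=0.0, phase0_range=0.0,
            phase1_range=0.0, baseline_amplitude=0.0, shift_jitter_sd=0.0, seed=0,
        )
        one = nm.simulate_spectrum_set(
            nm.StudyDesign(base_concentrations={"Alanine": 1.0}, **kw),
            intracellular_library, n_points=4096, water_height=0.0, tsp_height=0.0,
        )
        two = nm.simulate_spectrum_set(
            nm.StudyDesign(base_concentrations={"Alanine": 2.0}, **kw),
            intracellular_library, n_points=4096, water_height=0.0, tsp_height=0.0,
        )
        np.testing.assert_allclose(two.data[0], 2 * one.data[0], rtol=1e-12)

    def test_group_effect_scales_window_area(self, intracellular_library):
        design = nm.StudyDesign(
            n_control=2, n_knockdown=2,
            base_concentrations={"Alanine": 1.0}, log2_effects={"Alanine": -1.0},
            biological_cv=0.0, dilution_range=(1, 1), noise_sd=0.0,
            phase0_range=0.0, phase1_range=0.0, baseline_amplitude=0.0,
            shift_jitter_sd=0.0, seed=0,
        )
        sset = nm.simulate_spectrum_set(
            design, intracellular_library, n_points=16384, water_height=0.0,
            tsp_height=0.0,
        )
        mask = window_mask(sset.ppm, [(1.40, 1.56)])
        a_ctrl = np.trapezoid(sset.data[0].real[mask], sset.ppm[mask])
        a_kd = np.trapezoid(sset.data[-1].real[mask], sset.ppm[mask])
        assert a_kd / a_ctrl == pytest.approx(0.5, rel=1e-6)

    def test_truth_block_records_per_sample_parameters(self, default_sim_set):
        truth = default_sim_set.truth
        assert len(truth["samples"]) == default_sim_set.n_samples
        rec = truth["samples"][0]
        assert set(rec) >= {"dilution", "phase0", "phase1", "shift", "concentrations"}

    def test_unknown_metabolite_rejected(self, intracellular_library):
        design = nm.StudyDesign(base_concentrations={"Unobtainium": 1.0})
        with pytest.raises(ValueError, match="Unobtainium"):
            nm.simulate_spectrum_set(design, intracellular_library, n_points=4096)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            nm.StudyDesign(n_control=1)
        with pytest.raises(ValueError):
            nm.StudyDesign(dilution_range=(2.0, 0.5))
        with pytest.raises(ValueError):
            nm.StudyDesign(log2_effects={"NotInPanel": 1.0})


class TestSpectrumSetIO:
    def test_complex_round_trip_with_truth(self, tmp_path, clean_design,
                                           intracellular_library):
        sset = nm.simulate_spectrum_set(clean_design, intracellular_library,
                                        n_points=4096)
        nm.write_spectrum_set(sset, tmp_path / "s")
        back = nm.read_spectrum_set(tmp_path / "s")
        np.testing.assert_array_equal(back.ppm, sset.ppm)
        np.testing.assert_array_equal(back.data, sset.data)
        assert back.samples == sset.samples
        assert back.truth == sset.truth

    def test_real_round_trip_preserves_order(self, tmp_path):
        ppm = np.linspace(-0.5, 10.0, 64)
        data = np.arange(2 * 64, dtype=float).reshape(2, 64)
        sset = nm.SpectrumSet(
            ppm, data, [nm.SampleMeta("b", "knockdown"), nm.SampleMeta("a", "control")]
        )
        back = nm.read_spectrum_set(nm.write_spectrum_set(sset, tmp_path / "r")[0].with_suffix(""))
        assert [s.sample_id for s in back.samples] == ["b", "a"]
        np.testing.assert_array_equal(back.data, data)

    def test_truncated_file_is_format_error(self, tmp_path, clean_design,
                                            intracellular_library):
        sset = nm.simulate_spectrum_set(clean_design, intracellular_library,
                                        n_points=4096)
        tsv, _ = nm.write_spectrum_set(sset, tmp_path / "t")
        lines = tsv.read_text().splitlines()
        tsv.write_text("\n".join([lines[0]] + [ln.rsplit("\t", 2)[0] for ln in lines[1:]]))
        with pytest.raises(nm.spectra.SpectrumFormatError):
            nm.read_spectrum_set(tmp_path / "t")

    def test_missing_sidecar_is_format_error(self, tmp_path):
        (tmp_path / "x.tsv").write_text("ppm\ta\n0\t1\n")
        with pytest.raises(nm.spectra.SpectrumFormatError):
            nm.read_spectrum_set(tmp_path / "x")
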