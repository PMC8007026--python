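"""Phase, baseline, referencing, trimming and PQN against simulator truth."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.pipeline import Pipeline

import nmrmetab as nm
from nmrmetab.preprocess import asls_baseline, retained_mask


def _angdiff(a, b):
    return (a - b + 180.0) % 360.0 - 180.0


@pytest.fixture(scope="module")
def phase_error_set(intracellular_library):
    """Spectra with known (phi0, phi1) and no other artifacts."""
    design = nm.StudyDesign(
        phase0_range=45.0, phase1_range=20.0, biological_cv=0.0,
        dilution_range=(1, 1), noise_sd=0.0, baseline_amplitude=0.0,
        shift_jitter_sd=0.0, seed=11,
    )
    return nm.simulate_spectrum_set(design, intracellular_library, n_points=16384)


class TestPhaseCorrect:
    def test_zero_phase_identity(self, clean_design, intracellular_library):
        sset = nm.simulate_spectrum_set(clean_design, intracellular_library,
                                        n_points=16384)
        corrected, p0, p1 = nm.phase_correct(sset.data[0])
        assert abs(_angdiff(p0, 0)) < 0.5
        assert abs(p1) < 1.0
        scale = np.abs(sset.data[0]).max()
        np.testing.assert_allclose(corrected, sset.data[0].real, atol=0.005 * scale)

    def test_known_phase_recovered_within_2_degrees(self, clean_design,
                                                    intracellular_library):
        sset = nm.simulate_spectrum_set(clean_design, intracellular_library,
                                        n_points=16384)
        n = sset.ppm.size
        frac = np.arange(n) / (n - 1)
        spec = sset.data[0] * np.exp(1j * np.deg2rad(30.0 + 10.0 * frac))
        corrected, p0, p1 = nm.phase_correct(spec)
        assert abs(_angdiff(p0, 30.0)) < 2.0
        assert abs(p1 - 10.0) < 2.0
        # peak symmetry restored: corrected matches the unphased original
        np.testing.assert_allclose(corrected, sset.data[0].real,
                                   atol=0.02 * np.abs(sset.data[0]).max())

    def test_simulated_phase_errors_recovered(self, phase_error_set):
        for i in range(phase_error_set.n_samples):
            tr = phase_error_set.truth["samples"][i]
            _, p0, p1 = nm.phase_correct(phase_error_set.data[i])
            assert abs(_angdiff(p0, tr["phase0"])) < 2.0
            assert abs(p1 - tr["phase1"]) < 2.0

    def test_fixed_point(self, phase_error_set):
        spec = phase_error_set.data[0]
        n = spec.size
        frac = np.arange(n) / (n - 1)
        corrected, p0, p1 = nm.phase_correct(spec)
        rotated = spec * np.exp(-1j * np.deg2rad(p0 + p1 * frac))
        again, q0, q1 = nm.phase_correct(rotated)
        assert abs(_angdiff(q0, 0)) < 1.0 and abs(q1) < 2.0
        np.testing.assert_allclose(again, corrected,
                                   atol=0.02 * np.abs(corrected).max())

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            nm.phase_correct(np.zeros(4096, dtype=complex))


class TestBaselineCorrect:
    def test_linear_ramp_removed(self):
        rng = np.random.default_rng(0)
        n = 4096
        ramp = np.linspace(0.0, 5.0, n)
        noise = rng.normal(0, 0.01, n)
        corrected, baseline = nm.baseline_correct(ramp + noise)
        assert np.abs(corrected).max() < 0.05 * 5.0

    def test_conservation_exact(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 2048) + np.linspace(0, 3, 2048)
        corrected, baseline = nm.baseline_correct(y)
        np.testing.assert_allclose(corrected + baseline, y, rtol=0, atol=1e-12)

    def test_zero_baseline_input_unchanged(self):
        x = np.linspace(-1, 1, 4096)
        peak = 1.0 / (1.0 + (x / 0.01) ** 2)
        corrected, _ = nm.baseline_correct(peak)
        assert np.abs(corrected - peak).max() < 0.02

    def test_signal_free_region_centred_on_zero(self, default_sim_set):
        spec, p0, p1 = nm.phase_correct(default_sim_set.data[0])
        corrected, _ = nm.baseline_correct(spec)
        quiet = (default_sim_set.ppm > 9.3) & (default_sim_set.ppm < 9.9)
        dilution = default_sim_set.truth["samples"][0]["dilution"]
        noise_sd = 0.01 * dilution
        # the strongly asymmetric weights (p = 0.001) pin the baseline near
        # the lower noise envelope, leaving a positive offset of ~2 sigma
        assert abs(corrected[quiet].mean()) < 3 * noise_sd

    def test_smoothness_parameter_sets_scale(self):
        y = np.sin(np.linspace(0, 4 * np.pi, 4096))
        stiff = asls_baseline(y, lam=1e12)
        loose = asls_baseline(y, lam=1e4)
        assert np.abs(y - loose).max() < np.abs(y - stiff).max()


class TestReferenceToTsp:
    def test_known_shift_removed(self, intracellular_library, small_panel):
        design = nm.StudyDesign(
            base_concentrations=small_panel, log2_effects={}, biological_cv=0.0,
            dilution_range=(1, 1), noise_sd=0.001, phase0_range=0.0,
            phase1_range=0.0, baseline_amplitude=0.0, shift_jitter_sd=0.02, seed=2,
        )
        sset = nm.simulate_spectrum_set(design, intracellular_library, n_points=16384)
        step = sset.ppm[1] - sset.ppm[0]
        for i in range(sset.n_samples):
            tr = sset.truth["samples"][i]
            shifted, applied = nm.reference_to_tsp(sset.ppm, sset.data[i].real)
            assert applied == pytest.approx(-tr["shift"], abs=step)
            win = np.flatnonzero(np.abs(sset.ppm) <= 0.3)
            apex = sset.ppm[win[np.argmax(shifted[win])]]
            assert abs(apex) <= step

    def test_already_referenced_shift_is_zero(self, clean_design, intracellular_library):
        sset = nm.simulate_spectrum_set(clean_design, intracellular_library,
                                        n_points=8192)
        _, applied = nm.reference_to_tsp(sset.ppm, sset.data[0].real)
        step = sset.ppm[1] - sset.ppm[0]
        assert abs(applied) < step

    def test_missing_tsp_is_error(self):
        ppm = np.linspace(-0.5, 10, 8192)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="TSP"):
            nm.reference_to_tsp(ppm, rng.normal(0, 1e-3, ppm.size))


class TestTrimAndExclude:
    def test_default_retained_support(self, clean_design, intracellular_library):
        sset = nm.simulate_spectrum_set(clean_design, intracellular_library,
                                        n_points=8192)
        trimmed = nm.trim_and_exclude(sset)
        ppm = trimmed.ppm
        assert ppm.min() >= 0.6 and ppm.max() < 9.0
        assert not np.any((ppm >= 4.5) & (ppm < 5.0))

    def test_identity_when_nothing_dropped(self, clean_design, intracellular_library):
        sset = nm.simulate_spectrum_set(clean_design, intracellular_library,
                                        n_points=4096)
        out = nm.trim_and_exclude(sset, keep=(-1.0, 11.0), drop=())
        np.testing.assert_array_equal(out.ppm, sset.ppm)
        np.testing.assert_array_equal(out.data, sset.data)

    def test_point_count_matches_direct_count(self, clean_design,
                                              intracellular_library):
        sset = nm.simulate_spectrum_set(clean_design, intracellular_library,
                                        n_points=4096)
        expected = int(
            np.sum(
                ((sset.ppm >= 0.6) & (sset.ppm < 9.0))
                & ~((sset.ppm >= 4.5) & (sset.ppm < 5.0))
            )
        )
        assert nm.trim_and_exclude(sset).ppm.size == expected

    def test_empty_result_is_error(self, clean_design, intracellular_library):
        sset = nm.simulate_spectrum_set(clean_design, intracellular_library,
                                        n_points=4096)
        with pytest.raises(ValueError):
            nm.trim_and_exclude(sset, keep=(0.6, 9.0), drop=((0.0, 10.0),))


class TestPqn:
    def _toy_set(self):
        ppm = np.linspace(0.6, 4.4, 512)
        base = np.exp(-((ppm - 2.0) ** 2) / 0.02) + 0.5 * np.exp(
            -((ppm - 3.5) ** 2) / 0.01
        )
        data = np.vstack([base, base, 2 * base, 0.25 * base])
        samples = [
            nm.SampleMeta("c0", "control"),
            nm.SampleMeta("c1", "control"),
            nm.SampleMeta("k0", "knockdown"),
            nm.SampleMeta("k1", "knockdown"),
        ]
        return nm.SpectrumSet(ppm, data, samples)

    def test_identical_samples_equal_factors(self):
        sset = self._toy_set()
        out, factors = nm.pqn_normalize(sset)
        assert factors[0] == pytest.approx(factors[1])
        np.testing.assert_allclose(out.data[0], out.data[1])

    def test_scaled_sample_factor_ratio_exact(self):
        out, factors = nm.pqn_normalize(self._toy_set())
        assert factors[2] / factors[0] == pytest.approx(2.0)
        assert factors[3] / factors[0] == pytest.approx(0.25)
        np.testing.assert_allclose(out.data[2], out.data[0], rtol=1e-12)

    def test_idempotent_with_unit_factors(self):
        out, _ = nm.pqn_normalize(self._toy_set())
        again, factors = nm.pqn_normalize(out)
        np.testing.assert_allclose(factors, 1.0, atol=1e-12)
        np.testing.assert_allclose(again.data, out.data, rtol=1e-12)

    def test_zero_reference_rejected(self):
        ppm = np.linspace(0.6, 4.4, 64)
        data = np.vstack([np.full(64, 1e-12)] * 4)
        samples = [nm.SampleMeta(f"s{i}", "control") for i in range(4)]
        sset = nm.SpectrumSet(ppm, data, samples)
        out, factors = nm.pqn_normalize(sset)  # tiny but positive reference works
        assert np.all(factors > 0)
        with pytest.raises(ValueError):
            nm.pqn_normalize(
                nm.SpectrumSet(ppm, -data, samples)
            )

    def test_simulated_dilutions_recovered(self, preprocessed_set, default_sim_set):
        _, report = preprocessed_set
        factors = np.array([r["pqn_factor"] for r in report.samples])
        truth = np.array([t["dilution"] for t in default_sim_set.truth["samples"]])
        f = factors / np.exp(np.mean(np.log(factors)))
        d = truth / np.exp(np.mean(np.log(truth)))
        assert np.corrcoef(f, d)[0, 1] >= 0.98
        assert np.median(np.abs(f - d) / d) <= 0.05


class TestSklearnInterface:
    def test_pipeline_composition(self, default_sim_set):
        sset = default_sim_set
        pipe = Pipeline(
            [
                ("phase", nm.PhaseCorrector()),
                ("baseline", nm.BaselineCorrector()),
                ("reference", nm.TspReferencer(sset.ppm)),
                ("trim", nm.RegionTrimmer(sset.ppm)),
                ("pqn", nm.PqnNormalizer()),
            ]
        )
        groups = sset.groups()
        out = pipe.fit_transform(sset.data, groups)
        trimmer = pipe.named_steps["trim"]
        assert out.shape == (sset.n_samples, trimmer.ppm_out_.size)
        assert np.isrealobj(out)
        assert pipe.named_steps["pqn"].factors_.shape == (sset.n_samples,)

    def test_matches_function_chain(self, default_sim_set, preprocessed_set):
        proc, _ = preprocessed_set
        pipe = Pipeline(
            [
                ("phase", nm.PhaseCorrector()),
                ("baseline", nm.BaselineCorrector()),
                ("reference", nm.TspReferencer(default_sim_set.ppm)),
                ("trim", nm.RegionTrimmer(default_sim_set.ppm)),
                ("pqn", nm.PqnNormalizer()),
            ]
        )
        out = pipe.fit_transform(default_sim_set.data, default_sim_set.groups())
        np.testing.assert_allclose(out, proc.data, rtol=1e-10, atol=1e-12)

    def test_estimators_clone_and_get_params(self):
        est = nm.BaselineCorrector(lam=1e6, p=0.01)
        params = est.get_params()
        assert params["lam"] == 1e6 and params["p"] == 0.01
        twin = clone(est)
        assert twin.get_params() == params

    def test_retained_mask_half_open(self):
        ppm = np.array([0.59, 0.6, 4.49, 4.5, 4.99, 5.0, 8.99, 9.0])
        mask = retained_mask(ppm)
        np.testing.assert_array_equal(
            mask, [False, True, True, False, False, True, True, False]
        )
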