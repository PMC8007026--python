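import warnings

import numpy as np
import pytest

import nmrmetab as nm

warnings.filterwarnings("ignore", message="Precision loss occurred")


@pytest.fixture(scope="session")
def intracellular_library():
    return nm.load_library(nm.packaged_library_path("intracellular"), "intracellular")


@pytest.fixture(scope="session")
def extracellular_library():
    return nm.load_library(nm.packaged_library_path("extracellular"), "extracellular")


@pytest.fixture(scope="session")
def pathway_db():
    return nm.load_pathway_db(nm.packaged_library_path("pathways"))


@pytest.fixture(scope="session")
def windows(intracellular_library):
    return nm.build_assignment_windows(intracellular_library, half_width=0.02)


@pytest.fixture(scope="session")
def small_panel():
    return {"Alanine": 0.9, "Lactate": 3.9, "Formate": 0.3}


@pytest.fixture(scope="session")
def clean_design(small_panel):
    """All stochastic artifacts off: bitwise-reproducible spectra."""
    return nm.StudyDesign(
        n_control=2,
        n_knockdown=2,
        base_concentrations=small_panel,
        log2_effects={},
        biological_cv=0.0,
        dilution_range=(1, 1),
        noise_sd=0.0,
        phase0_range=0.0,
        phase1_range=0.0,
        baseline_amplitude=0.0,
        shift_jitter_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def default_sim_set(intracellular_library):
    """One full-default simulated study, shared across read-only tests."""
    return nm.simulate_spectrum_set(
        nm.StudyDesign(seed=7), intracellular_library, n_points=8192
    )


@pytest.fixture(scope="session")
def preprocessed_set(default_sim_set):
    proc, report = nm.preprocess_spectrum_set(default_sim_set)
    return proc, report


def window_mask(ppm: np.ndarray, intervals) -> np.ndarray:
    mask = np.zeros(ppm.size, dtype=bool)
    for lo, hi in intervals:
        mask |= (ppm >= lo) & (ppm < hi)
    return mask
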