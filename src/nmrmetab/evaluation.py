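"""Self-contained recovery benchmarks against simulator ground truth.

Each function simulates a study under stated conditions, runs the standard
pipeline, and scores the result against the recorded truth.  They are used
by the validation test suite and the reproduction script; problem sizes are
kept at desk scale (8192-point axes unless noted).
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from .library import AssignmentTable, build_assignment_windows, load_library, packaged_library_path
from .preprocess import phase_correct, preprocess_spectrum_set, retained_mask
from .quantify import group_stats, integrate
from .simulate import DEFAULT_PANEL, StudyDesign, simulate_spectrum_set
from .spectra import SpectrumSet
from .stocsy import stocsy_profile
from .enrichment import hypergeom_upper_tail

__all__ = [
    "pqn_dilution_recovery",
    "fold_change_recovery",
    "stocsy_fidelity",
    "stocsy_null_false_positives",
    "phase_recovery",
    "lorentzian_integration_check",
    "hypergeom_exhaustive_check",
    "trimming_check",
]


def _intracellular():
    return load_library(packaged_library_path("intracellular"), "intracellular")


def _panel_windows(names, half_width=0.02):
    full = build_assignment_windows(_intracellular(), half_width=half_width)
    return AssignmentTable({k: full.entries[k] for k in names}, half_width)


def _geometric_centre(x):
    return x / np.exp(np.mean(np.log(x)))


def pqn_dilution_recovery(seed: int, n_points: int = 8192,
                          dilution_range=(0.5, 2.0)) -> dict:
    """Simulate 2x5 samples with log-uniform dilutions and compare the PQN
    factors with the true dilution factors (both geometric-mean centred)."""
    library = _intracellular()
    design = StudyDesign(seed=seed, dilution_range=tuple(dilution_range))
    sset = simulate_spectrum_set(design, library, n_points=n_points)
    _, report = preprocess_spectrum_set(sset)
    factors = np.array([rec["pqn_factor"] for rec in report.samples])
    truth = np.array([rec["dilution"] for rec in sset.truth["samples"]])
    f, d = _geometric_centre(factors), _geometric_centre(truth)
    return {
        "pearson_r": float(np.corrcoef(f, d)[0, 1]),
        "median_relative_error": float(np.median(np.abs(f - d) / d)),
        "n_samples": int(sset.n_samples),
    }


def fold_change_recovery(seed: int, n_reps: int = 50, n_points: int = 16384,
                         tol: float = 0.15) -> dict:
    """Repeatedly estimate log2 fold changes of the default knockdown design
    (cysteine -1.0, lactate +0.4, others null) and count replicates where
    every metabolite lands within ``tol`` of its true effect."""
    library = _intracellular()
    windows = _panel_windows(DEFAULT_PANEL)
    successes = 0
    worst = []
    for rep in range(n_reps):
        design = StudyDesign(seed=seed + rep)
        sset = simulate_spectrum_set(design, library, n_points=n_points)
        proc, _ = preprocess_spectrum_set(sset)
        stats = group_stats(integrate(proc, windows))
        fc = dict(zip(stats["metabolite"], stats["log2_fc"]))
        errors = {
            name: fc[name] - design.log2_effects.get(name, 0.0) for name in fc
        }
        max_err = max(abs(e) for e in errors.values())
        worst.append(max_err)
        if max_err <= tol:
            successes += 1
    return {
        "success_rate": successes / n_reps,
        "n_reps": n_reps,
        "median_worst_abs_error": float(np.median(worst)),
    }


def _real_valued(design: StudyDesign, library, n_points: int) -> SpectrumSet:
    sset = simulate_spectrum_set(design, library, n_points=n_points)
    return SpectrumSet(sset.ppm, sset.data.real, sset.samples, sset.truth)


def stocsy_fidelity(seed: int, n_points: int = 8192) -> dict:
    """Noiseless concentration-only variation: the driver point must hit
    r = 1 exactly and every point in the driver metabolite's own windows
    must correlate at r >= 0.99."""
    library = _intracellular()
    design = StudyDesign(
        seed=seed, biological_cv=0.2, dilution_range=(1, 1), noise_sd=0.0,
        phase0_range=0.0, phase1_range=0.0, baseline_amplitude=0.0,
        shift_jitter_sd=0.0, log2_effects={},
    )
    proc, _ = preprocess_spectrum_set(_real_valued(design, library, n_points))
    profile = stocsy_profile(proc, 1.33)
    j = int(np.argmin(np.abs(proc.ppm - profile.driver)))
    windows = _panel_windows(["Lactate"])
    mask = np.zeros(proc.ppm.size, dtype=bool)
    for lo, hi in windows.entries["Lactate"]:
        mask |= (proc.ppm >= lo) & (proc.ppm < hi)
    return {
        "driver_r": float(profile.r[j]),
        "min_intra_metabolite_r": float(profile.r[mask].min()),
    }


def stocsy_null_false_positives(seed: int, n_reps: int = 100,
                                n_points: int = 8192) -> dict:
    """Two independently varying metabolites, n = 10: fraction of points in
    the non-driver metabolite's windows that pass Bonferroni at alpha 0.05
    from the driver of the other metabolite, pooled over replicates."""
    library = _intracellular()
    windows = _panel_windows(["Alanine", "Lactate"])
    flagged = 0
    total = 0
    for rep in range(n_reps):
        design = StudyDesign(
            seed=seed + rep,
            base_concentrations={"Alanine": 0.9, "Lactate": 3.9},
            log2_effects={}, biological_cv=0.2, dilution_range=(0.8, 1.25),
            noise_sd=0.01, phase0_range=0.0, phase1_range=0.0,
            baseline_amplitude=0.0, shift_jitter_sd=0.0,
        )
        proc, _ = preprocess_spectrum_set(_real_valued(design, library, n_points))
        profile = stocsy_profile(proc, 1.48, alpha=0.05, method="bonferroni")
        mask = np.zeros(proc.ppm.size, dtype=bool)
        for lo, hi in windows.entries["Lactate"]:
            mask |= (proc.ppm >= lo) & (proc.ppm < hi)
        flagged += int(profile.significant[mask].sum())
        total += int(mask.sum())
    return {"false_positive_fraction": flagged / total, "n_reps": n_reps}


def phase_recovery(seed: int, n_points: int = 16384) -> dict:
    """Recover known zero/first-order phase errors up to (45, 20) degrees on
    otherwise artifact-free spectra."""
    library = _intracellular()
    design = StudyDesign(
        seed=seed, phase0_range=45.0, phase1_range=20.0, biological_cv=0.0,
        dilution_range=(1, 1), noise_sd=0.0, baseline_amplitude=0.0,
        shift_jitter_sd=0.0,
    )
    sset = simulate_spectrum_set(design, library, n_points=n_points)
    err0, err1 = [], []
    for i in range(sset.n_samples):
        tr = sset.truth["samples"][i]
        _, p0, p1 = phase_correct(sset.data[i])
        err0.append(abs((p0 - tr["phase0"] + 180.0) % 360.0 - 180.0))
        err1.append(abs(p1 - tr["phase1"]))
    return {
        "max_phase0_error_deg": float(max(err0)),
        "max_phase1_error_deg": float(max(err1)),
        "n_spectra": sset.n_samples,
    }


def lorentzian_integration_check() -> dict:
    """Trapezoidal integration against closed forms: a unit rectangle and a
    Lorentzian of area pi*A*w over a window of 200 half-widths."""
    from .quantify import integrate as _integrate
    from .spectra import SampleMeta

    ppm = np.linspace(0.995, 1.105, 111)
    rect = np.where((ppm >= 1.0) & (ppm <= 1.1), 1.0, 0.0)
    sset = SpectrumSet(
        ppm, np.vstack([rect] * 2), [SampleMeta("a", "control"), SampleMeta("b", "control")]
    )
    # window aligned to the rectangle support so the trapezoid is exact
    rect_area = float(
        _integrate(sset, AssignmentTable({"r": [(0.9995, 1.1005)]}, 0.05)).values["r"].iloc[0]
    )

    A, w = 3.0, 0.003
    ppm2 = np.linspace(2.0 - 100 * w, 2.0 + 100 * w, 20001)
    lor = A / (1.0 + ((ppm2 - 2.0) / w) ** 2)
    sset2 = SpectrumSet(
        ppm2, np.vstack([lor] * 2), [SampleMeta("a", "control"), SampleMeta("b", "control")]
    )
    lor_area = float(
        _integrate(sset2, AssignmentTable({"l": [(ppm2[0], ppm2[-1] + 1e-9)]}, 0.3))
        .values["l"].iloc[0]
    )
    return {
        "rectangle_abs_error": abs(rect_area - 0.1),
        "lorentzian_relative_error": abs(lor_area - math.pi * A * w) / (math.pi * A * w),
    }


def hypergeom_exhaustive_check(max_N: int = 25) -> dict:
    """Sweep every valid (k, K, n, N) with N <= max_N against exact rational
    tail sums; returns the largest absolute deviation."""
    worst = 0.0
    count = 0
    for N in range(1, max_N + 1):
        for n in range(N + 1):
            for K in range(N + 1):
                denom = math.comb(N, K)
                for k in range(min(K, n) + 1):
                    exact = float(
                        sum(
                            Fraction(math.comb(n, j) * math.comb(N - n, K - j), denom)
                            for j in range(k, min(K, n) + 1)
                        )
                    )
                    worst = max(worst, abs(hypergeom_upper_tail(k, K, n, N) - exact))
                    count += 1
    return {"max_abs_error": worst, "instances": count}


def trimming_check(n_points: int = 8192) -> dict:
    """Default trim on a [-0.5, 10] axis retains exactly [0.6, 4.5) u [5.0, 9.0)."""
    ppm = np.linspace(-0.5, 10.0, n_points)
    mask = retained_mask(ppm)
    kept = ppm[mask]
    expected = int(
        np.sum(((ppm >= 0.6) & (ppm < 9.0)) & ~((ppm >= 4.5) & (ppm < 5.0)))
    )
    return {
        "retained_points": int(mask.sum()),
        "expected_points": expected,
        "water_band_points": int(np.sum((kept >= 4.5) & (kept < 5.0))),
        "outside_keep_points": int(np.sum((kept < 0.6) | (kept >= 9.0))),
    }
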