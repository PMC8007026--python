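"""Spectral preprocessing: phase, baseline, TSP referencing, trimming, PQN.

The standard chain, in order, is

    phase -> baseline -> TSP reference -> trim (keep 0.6-9.0, drop 4.5-5.0) -> PQN

Low-level per-spectrum functions carry the numerics; sklearn-style
transformers (:class:`PhaseCorrector` etc.) wrap them so the chain composes
with ``sklearn.pipeline.Pipeline`` on an (n_samples, n_points) matrix, and
:func:`preprocess_spectrum_set` applies the whole chain to a
:class:`~nmrmetab.spectra.SpectrumSet`, returning a
:class:`PreprocessingReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.optimize
import scipy.linalg
import scipy.sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import SampleMeta, SpectrumSet

__all__ = [
    "phase_correct",
    "asls_baseline",
    "baseline_correct",
    "reference_to_tsp",
    "trim_and_exclude",
    "pqn_normalize",
    "preprocess_spectrum_set",
    "PreprocessingReport",
    "PhaseCorrector",
    "BaselineCorrector",
    "TspReferencer",
    "RegionTrimmer",
    "PqnNormalizer",
]

DEFAULT_KEEP = (0.6, 9.0)
DEFAULT_DROP = ((4.5, 5.0),)


# ---------------------------------------------------------------- phasing


def _detrended_negativity(re: np.ndarray, nseg: int = 16) -> float:
    """Squared negative intensity after removing a coarse per-segment floor.

    The floor (10th percentile over long segments, linearly interpolated)
    absorbs smooth baseline drift while leaving the narrow negative
    dispersion lobes of mis-phased peaks intact, so the penalty responds to
    phase error rather than to baseline.  Segments must be much wider than a
    line width for the lobes to survive the percentile.
    """
    n = re.size
    m = n - n % nseg
    seg = re[:m].reshape(nseg, -1)
    floor = np.percentile(seg, 10, axis=1)
    centers = (np.arange(nseg) + 0.5) * (m // nseg)
    detr = re - np.interp(np.arange(n), centers, floor)
    neg = np.minimum(detr, 0.0)
    return float(neg @ neg)


def _neg_penalty(spec: np.ndarray, frac: np.ndarray, phi0: float, phi1: float) -> float:
    re = (spec * np.exp(-1j * np.deg2rad(phi0 + phi1 * frac))).real
    return _detrended_negativity(re)


def phase_correct(
    spec: np.ndarray,
    phi0_grid: float = 15.0,
    phi1_max: float = 60.0,
) -> tuple[np.ndarray, float, float]:
    """Automatic zero/first-order phase correction of one complex spectrum.

    Applies ``exp(-i (phi0 + phi1 * x))`` with ``x`` the fractional position
    along the axis, choosing the angles that minimize the squared negative
    intensity of the real channel (grid search + Nelder-Mead refinement).
    Returns ``(real_spectrum, phi0_deg, phi1_deg)``.
    """
    spec = np.asarray(spec)
    if not np.any(spec):
        raise ValueError("cannot phase an all-zero spectrum")
    scale = float(np.abs(spec).max())
    z = spec / scale
    n = z.size
    frac = np.arange(n) / (n - 1)

    best = (np.inf, 0.0, 0.0)
    abs_sum = float(np.sum(np.abs(z)))
    for p1 in np.arange(-phi1_max, phi1_max + 1e-9, phi0_grid):
        z1 = z * np.exp(-1j * np.deg2rad(p1) * frac)
        for p0 in np.arange(-180.0, 180.0, phi0_grid):
            c, s = np.cos(np.deg2rad(p0)), np.sin(np.deg2rad(p0))
            re = z1.real * c + z1.imag * s
            # reject the degenerate rotation that empties the real channel
            # (reachable when the input is purely real/absorptive)
            if np.sum(np.abs(re)) < 0.1 * abs_sum:
                continue
            val = _detrended_negativity(re)
            if val < best[0]:
                best = (val, p0, p1)

    phi0, phi1 = _local_fit_refine(z, frac, best[1], best[2])
    if phi0 is None:
        res = scipy.optimize.minimize(
            lambda p: _neg_penalty(z, frac, p[0], p[1]),
            x0=np.array(best[1:]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-14, "maxiter": 400},
        )
        phi0, phi1 = float(res.x[0]), float(res.x[1])
    # canonical reporting range
    phi0 = (phi0 + 180.0) % 360.0 - 180.0
    corrected = (spec * np.exp(-1j * np.deg2rad(phi0 + phi1 * frac))).real
    return corrected, phi0, phi1


def _fit_one_peak(z, i, hw, guess):
    """Fit ``A e^{i phi} / (1 + iu)`` plus a local complex linear baseline in
    a tight window; returns (phi, A, rms) or None if the fit is implausible
    (broad or off-centre fits reject e.g. the residual-water plateau)."""
    lo, hi = max(0, i - hw), min(z.size, i + hw + 1)
    x = np.arange(lo, hi, dtype=float)
    zz = z[lo:hi]
    t = (x - i) / hw

    def resid(p):
        c, w, amp, phi, ar, ai, br, bi = p
        u = (x - c) / w
        f = amp * np.exp(1j * np.deg2rad(phi)) / (1 + 1j * u) + (ar + 1j * ai) + (
            br + 1j * bi
        ) * t
        r = f - zz
        return np.r_[r.real, r.imag]

    def jac(p):
        c, w, amp, phi, ar, ai, br, bi = p
        u = (x - c) / w
        L = 1.0 / (1.0 + 1j * u)
        e = np.exp(1j * np.deg2rad(phi))
        core = amp * e * 1j * L * L / w
        cols = [
            core,  # d/dc
            core * u,  # d/dw
            e * L,  # d/dA
            1j * amp * e * L * (np.pi / 180.0),  # d/dphi (degrees)
            np.ones_like(u),  # d/dar
            1j * np.ones_like(u),  # d/dai
            t.astype(complex),  # d/dbr
            1j * t,  # d/dbi
        ]
        J = np.column_stack(cols)
        return np.vstack([J.real, J.imag])

    p0 = [
        float(i),
        hw / 4.0,
        float(np.abs(z[i])),
        guess,
        float(np.median(zz.real)),
        float(np.median(zz.imag)),
        0.0,
        0.0,
    ]
    try:
        res = scipy.optimize.least_squares(resid, p0, jac=jac, method="lm", max_nfev=100)
    except Exception:
        return None
    c, w, amp, phi = res.x[:4]
    w = abs(w)
    if amp <= 0 or not (0.5 <= w <= hw) or abs(c - i) > hw / 2:
        return None
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return float(phi), float(amp), rms


def _local_fit_refine(z, frac, phi0_coarse, phi1_coarse):
    """Refine (phi0, phi1) by fitting local phases of strong narrow peaks.

    Each strong peak is fit with a complex Lorentzian whose phase parameter
    measures the residual local phase exactly; a robust weighted straight
    line through (axis position, local phase) separates the zero- and
    first-order terms, which the negativity penalty alone leaves nearly
    degenerate when peaks cluster in one part of the spectrum.  Returns
    (None, None) when fewer than three usable peaks span the axis.
    """
    import scipy.signal

    n = z.size
    mag = np.abs(z)
    peaks, props = scipy.signal.find_peaks(
        mag, height=0.02 * mag.max(), distance=max(5, n // 2000)
    )
    order = np.argsort(props["peak_heights"])[::-1][:30]
    hw = max(8, n // 1200)
    ph, wt, fr = [], [], []
    for i in peaks[order]:
        guess = phi0_coarse + phi1_coarse * frac[i]
        out = _fit_one_peak(z, int(i), hw, guess)
        if out is None:
            continue
        phi, amp, rms = out
        phi += 360.0 * np.round((guess - phi) / 360.0)
        if abs(phi - guess) > 60:
            continue
        ph.append(phi)
        wt.append((amp / max(rms, 1e-12)) ** 2)
        fr.append(frac[i])
    if len(ph) < 3 or max(fr) - min(fr) < 0.1:
        return None, None
    ph, wt, fr = map(np.array, (ph, wt, fr))
    coef = np.array([phi0_coarse, phi1_coarse])
    for _ in range(3):  # weighted LS with outlier rejection
        A = np.column_stack([np.ones(fr.size), fr])
        w = np.sqrt(wt)
        coef, *_ = np.linalg.lstsq(A * w[:, None], ph * w, rcond=None)
        res = ph - A @ coef
        s = 1.4826 * np.median(np.abs(res)) + 1e-9
        keep = np.abs(res) < 3.5 * s
        if keep.all() or keep.sum() < 3:
            break
        ph, wt, fr = ph[keep], wt[keep], fr[keep]
    return float(coef[0]), float(coef[1])


# ---------------------------------------------------------------- baseline


def asls_baseline(
    y: np.ndarray, lam: float = 1e7, p: float = 0.001, niter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate (Whittaker smoother with
    asymmetric weights): points above the baseline get weight ``p``, points
    below ``1 - p``; ``lam`` penalizes the squared second difference in
    point-index units."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("spectrum too short for baseline estimation")
    D = scipy.sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    DtD = (lam * (D.T @ D)).tocsc()
    # symmetric banded form (upper) for solveh_banded
    ab0 = np.zeros((3, n))
    ab0[0, 2:] = DtD.diagonal(2)
    ab0[1, 1:] = DtD.diagonal(1)
    ab0[2, :] = DtD.diagonal(0)
    w = np.ones(n)
    z = y
    for _ in range(niter):
        ab = ab0.copy()
        ab[2, :] += w
        z = scipy.linalg.solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def baseline_correct(
    y: np.ndarray, lam: float = 1e7, p: float = 0.001, niter: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the AsLS baseline; returns ``(corrected, baseline)`` with
    ``corrected + baseline == input`` exactly."""
    z = asls_baseline(y, lam=lam, p=p, niter=niter)
    return y - z, z


# ---------------------------------------------------------------- referencing


def _noise_sd(y: np.ndarray) -> float:
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def reference_to_tsp(
    ppm: np.ndarray, y: np.ndarray, search_half: float = 0.3, min_snr: float = 5.0
) -> tuple[np.ndarray, float]:
    """Shift the axis so the TSP apex sits at exactly 0 ppm.

    The apex is located by parabolic interpolation over the three points
    around the maximum within ``+/- search_half`` ppm of 0; intensities are
    resampled onto the original grid by linear interpolation.  Returns
    ``(shifted_spectrum, shift_applied_ppm)``.
    """
    ppm = np.asarray(ppm, dtype=float)
    y = np.asarray(y, dtype=float)
    win = np.flatnonzero(np.abs(ppm) <= search_half)
    if win.size < 3:
        raise ValueError("no axis points in the TSP search window")
    j = win[np.argmax(y[win])]
    if y[j] < min_snr * _noise_sd(y) or j == 0 or j == y.size - 1:
        raise ValueError("TSP not found: no peak above the noise near 0 ppm")
    y0, y1, y2 = y[j - 1], y[j], y[j + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    dx = ppm[j + 1] - ppm[j]
    apex = ppm[j] + offset * dx
    shift = -apex
    shifted = np.interp(ppm - shift, ppm, y)
    return shifted, shift


# ---------------------------------------------------------------- trimming


def retained_mask(
    ppm: np.ndarray,
    keep: tuple[float, float] = DEFAULT_KEEP,
    drop: tuple[tuple[float, float], ...] = DEFAULT_DROP,
) -> np.ndarray:
    """Boolean mask of retained points; all intervals half-open ``[lo, hi)``."""
    ppm = np.asarray(ppm)
    mask = (ppm >= keep[0]) & (ppm < keep[1])
    for lo, hi in drop:
        mask &= ~((ppm >= lo) & (ppm < hi))
    return mask


def trim_and_exclude(
    sset: SpectrumSet,
    keep: tuple[float, float] = DEFAULT_KEEP,
    drop: tuple[tuple[float, float], ...] = DEFAULT_DROP,
) -> SpectrumSet:
    """Keep ``keep`` and remove every ``drop`` interval from axis and samples."""
    mask = retained_mask(sset.ppm, keep, drop)
    if not mask.any():
        raise ValueError("trimming removed every axis point")
    return SpectrumSet(sset.ppm[mask], sset.data[:, mask], list(sset.samples), truth=sset.truth)


# ---------------------------------------------------------------- PQN


def pqn_normalize(
    sset: SpectrumSet,
    reference_group: str = "control",
    reference_sample: str | None = None,
    floor_percentile: float = 5.0,
) -> tuple[SpectrumSet, np.ndarray]:
    """Probabilistic quotient normalization against a control-derived reference.

    Step 1: scale every spectrum to unit total (summed) intensity.
    Step 2: reference = point-wise median of the reference-group spectra
    (or one designated sample).  Step 3: per sample, factor = median of the
    point-wise sample/reference quotients over points where the reference
    exceeds its ``floor_percentile`` percentile.  Step 4: divide by the
    factor.  Returned factors are the product of both scalings, so
    ``raw = factor * normalized`` up to the quotient convention.
    """
    if sset.is_complex:
        raise ValueError("PQN expects phased (real) spectra")
    X = sset.data.astype(float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("non-positive total intensity; check preprocessing order")
    X1 = X / totals[:, None]
    if reference_sample is not None:
        ids = [s.sample_id for s in sset.samples]
        if reference_sample not in ids:
            raise ValueError(f"reference sample {reference_sample!r} not in set")
        ref = X1[ids.index(reference_sample)]
    else:
        idx = sset.group_index(reference_group)
        if idx.size == 0:
            raise ValueError(f"no samples in reference group {reference_group!r}")
        ref = np.median(X1[idx], axis=0)
    if not np.any(ref):
        raise ValueError("PQN reference is identically zero")
    floor = np.percentile(ref, floor_percentile)
    pts = (ref >= floor) & (ref > 0.0)
    if not pts.any():
        raise ValueError("no reference points above the intensity floor")
    quotients = X1[:, pts] / ref[pts]
    q = np.median(quotients, axis=1)
    factors = totals * q
    out = X1 / q[:, None]
    return (
        SpectrumSet(sset.ppm, out, list(sset.samples), truth=sset.truth),
        factors,
    )


# ---------------------------------------------------------------- full chain


@dataclass
class PreprocessingReport:
    """Per-sample corrections applied by the standard chain."""

    samples: list[dict] = field(default_factory=list)
    retained_region: list[tuple[float, float]] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def preprocess_spectrum_set(
    sset: SpectrumSet,
    keep: tuple[float, float] = DEFAULT_KEEP,
    drop: tuple[tuple[float, float], ...] = DEFAULT_DROP,
    pqn_reference_group: str = "control",
    pqn_reference_sample: str | None = None,
    baseline_lam: float = 1e7,
    baseline_p: float = 0.001,
) -> tuple[SpectrumSet, PreprocessingReport]:
    """Run phase -> baseline -> TSP reference -> trim -> PQN on a set."""
    records = [{"sample_id": s.sample_id} for s in sset.samples]
    X = np.empty((sset.n_samples, sset.ppm.size), dtype=float)
    for i in range(sset.n_samples):
        if sset.is_complex:
            xi, p0, p1 = phase_correct(sset.data[i])
        else:
            xi, p0, p1 = sset.data[i].real.astype(float), 0.0, 0.0
        xi, base = baseline_correct(xi, lam=baseline_lam, p=baseline_p)
        xi, shift = reference_to_tsp(sset.ppm, xi)
        X[i] = xi
        records[i].update(
            phase0=p0,
            phase1=p1,
            reference_shift=shift,
            baseline_params={"lam": baseline_lam, "p": baseline_p},
        )
    work = SpectrumSet(sset.ppm, X, list(sset.samples), truth=sset.truth)
    work = trim_and_exclude(work, keep=keep, drop=drop)
    work, factors = pqn_normalize(
        work,
        reference_group=pqn_reference_group,
        reference_sample=pqn_reference_sample,
    )
    for rec, f in zip(records, factors):
        rec["pqn_factor"] = float(f)
    # retained support as maximal intervals of the kept axis
    region = []
    lo, hi = keep
    for dlo, dhi in sorted(drop):
        if dlo > lo:
            region.append((lo, min(dlo, hi)))
        lo = max(lo, dhi)
    if lo < hi:
        region.append((lo, hi))
    report = PreprocessingReport(
        samples=records,
        retained_region=region,
        parameters={
            "keep": list(keep),
            "drop": [list(d) for d in drop],
            "pqn_reference_group": pqn_reference_group,
            "pqn_reference_sample": pqn_reference_sample,
            "baseline_lam": baseline_lam,
            "baseline_p": baseline_p,
        },
    )
    return work, report


# ------------------------------------------------------- sklearn transformers


class PhaseCorrector(BaseEstimator, TransformerMixin):
    """Per-row automatic phase correction of a complex spectrum matrix.

    Stateless across samples: ``fit`` is a no-op; ``transform`` phases each
    row independently and records the angles in ``phase0_`` / ``phase1_``
    (degrees).
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X))
        out = np.empty(X.shape, dtype=float)
        phase0, phase1 = [], []
        for i in range(X.shape[0]):
            out[i], p0, p1 = phase_correct(X[i])
            phase0.append(p0)
            phase1.append(p1)
        self.phase0_ = np.array(phase0)
        self.phase1_ = np.array(phase1)
        return out


class BaselineCorrector(BaseEstimator, TransformerMixin):
    """Per-row asymmetric-least-squares baseline removal."""

    def __init__(self, lam: float = 1e7, p: float = 0.001, niter: int = 10):
        self.lam = lam
        self.p = p
        self.niter = niter

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        baselines = np.empty_like(X)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i], baselines[i] = baseline_correct(
                X[i], lam=self.lam, p=self.p, niter=self.niter
            )
        self.baselines_ = baselines
        return out


class TspReferencer(BaseEstimator, TransformerMixin):
    """Per-row axis referencing to the TSP apex; needs the shared ppm axis."""

    def __init__(self, ppm, search_half: float = 0.3, min_snr: float = 5.0):
        self.ppm = ppm
        self.search_half = search_half
        self.min_snr = min_snr

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(X)
        shifts = []
        for i in range(X.shape[0]):
            out[i], s = reference_to_tsp(
                np.asarray(self.ppm), X[i], self.search_half, self.min_snr
            )
            shifts.append(s)
        self.shifts_ = np.array(shifts)
        return out


class RegionTrimmer(BaseEstimator, TransformerMixin):
    """Column selection to the retained chemical-shift region."""

    def __init__(self, ppm, keep=DEFAULT_KEEP, drop=DEFAULT_DROP):
        self.ppm = ppm
        self.keep = keep
        self.drop = drop

    def fit(self, X=None, y=None):
        self.mask_ = retained_mask(np.asarray(self.ppm), self.keep, tuple(self.drop))
        if not self.mask_.any():
            raise ValueError("trimming removed every axis point")
        self.ppm_out_ = np.asarray(self.ppm)[self.mask_]
        return self

    def transform(self, X):
        if not hasattr(self, "mask_"):
            self.fit()
        return np.atleast_2d(np.asarray(X))[:, self.mask_]


class PqnNormalizer(BaseEstimator, TransformerMixin):
    """Probabilistic quotient normalization learned from reference rows.

    ``fit(X, y)`` takes group labels in ``y`` and stores the point-wise
    median of the unit-sum reference-group rows as ``reference_``;
    ``transform`` divides each row by its total intensity and its median
    quotient, recording combined factors in ``factors_``.
    """

    def __init__(self, reference_group: str = "control", floor_percentile: float = 5.0):
        self.reference_group = reference_group
        self.floor_percentile = floor_percentile

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        totals = X.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("non-positive total intensity")
        X1 = X / totals[:, None]
        if y is None:
            ref_rows = X1
        else:
            ref_rows = X1[np.asarray(y) == self.reference_group]
            if ref_rows.shape[0] == 0:
                raise ValueError(f"no rows labelled {self.reference_group!r}")
        self.reference_ = np.median(ref_rows, axis=0)
        if not np.any(self.reference_):
            raise ValueError("PQN reference is identically zero")
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        totals = X.sum(axis=1)
        X1 = X / totals[:, None]
        ref = self.reference_
        pts = (ref >= np.percentile(ref, self.floor_percentile)) & (ref > 0.0)
        q = np.median(X1[:, pts] / ref[pts], axis=1)
        self.factors_ = totals * q
        return X1 / q[:, None]
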