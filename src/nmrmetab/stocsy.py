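"""Statistical total correlation spectroscopy (STOCSY).

One spectral point (the *driver*) is correlated against every retained
point across samples; peaks belonging to the same molecule correlate near
|r| = 1, so the profile doubles as an identification aid.  Significance is
attached per point from the t distribution of the correlation coefficient
and adjusted for multiplicity (Bonferroni by default, Benjamini-Hochberg
optionally).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .spectra import SpectrumSet

__all__ = ["StocsyProfile", "stocsy_profile", "adjust_pvalues", "export_pseudo2d"]


@dataclass
class StocsyProfile:
    """Per-point correlation profile for one driver chemical shift."""

    driver: float  # driver position snapped to the axis (ppm)
    ppm: np.ndarray
    r: np.ndarray
    covariance: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    threshold_r: float
    alpha: float
    significant: np.ndarray
    false_positive_ratio: float
    method: str


def adjust_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Multiplicity adjustment: ``bonferroni`` (min(1, m*p)) or ``bh``
    (Benjamini-Hochberg step-up with monotonicity enforcement)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def _rank(X: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(X, axis=0)


def stocsy_profile(
    sset: SpectrumSet,
    driver_ppm: float,
    alpha: float = 0.05,
    threshold_r: float = 0.8,
    method: str = "bonferroni",
    correlation: str = "pearson",
) -> StocsyProfile:
    """Correlate the driver point against every point of a preprocessed set.

    ``driver_ppm`` snaps to the nearest axis point (ties to the lower ppm).
    p-values come from ``t = r sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of
    freedom; the driver point itself is exact (r = 1, p = 0).  A point is
    significant when ``p_adj < alpha`` and ``|r| >= threshold_r``.  The
    false-positive ratio reported is ``alpha * m / max(1, #significant)``.
    """
    if sset.n_samples < 4:
        raise ValueError("STOCSY needs at least 4 samples")
    X = sset.data.real.astype(float)
    ppm = sset.ppm
    dist = np.abs(ppm - driver_ppm)
    j0 = int(np.flatnonzero(dist == dist.min())[0])  # tie -> lower ppm
    if correlation == "spearman":
        X = _rank(X)
    elif correlation != "pearson":
        raise ValueError(f"unknown correlation flavour {correlation!r}")
    d = X[:, j0]
    if np.std(d) == 0:
        raise ValueError("driver point has zero variance across samples")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    dc = Xc[:, j0]
    cov = (dc @ Xc) / (n - 1)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / (sd[j0] * sd)
    r[~np.isfinite(r)] = 0.0  # zero-variance columns carry no information
    r = np.clip(r, -1.0, 1.0)
    r[j0] = 1.0
    df = n - 2
    r2 = np.minimum(r * r, 1.0 - 1e-15)
    t = np.abs(r) * np.sqrt(df / (1.0 - r2))
    p_raw = 2.0 * scipy.stats.t.sf(t, df)
    p_raw = np.clip(p_raw, 0.0, 1.0)
    p_raw[np.abs(r) >= 1.0] = 0.0
    p_raw[j0] = 0.0
    p_adj = adjust_pvalues(p_raw, method=method)
    significant = (p_adj < alpha) & (np.abs(r) >= threshold_r)
    fpr = alpha * p_raw.size / max(1, int(significant.sum()))
    return StocsyProfile(
        driver=float(ppm[j0]),
        ppm=ppm.copy(),
        r=r,
        covariance=cov,
        p_raw=p_raw,
        p_adj=p_adj,
        threshold_r=threshold_r,
        alpha=alpha,
        significant=significant,
        false_positive_ratio=fpr,
        method=method,
    )


def export_pseudo2d(
    profile: StocsyProfile, out_prefix: str | Path, header_comment: str | None = None
) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (ppm, r, covariance, p_raw, p_adj, significant)
    and ``<prefix>.png`` (covariance trace coloured by |r|)."""
    out_prefix = Path(out_prefix)
    tsv = out_prefix.with_suffix(".tsv")
    png = out_prefix.with_suffix(".png")
    with tsv.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# driver_ppm={profile.driver:.6f} method={profile.method} "
                 f"alpha={profile.alpha} threshold_r={profile.threshold_r}\n")
        fh.write("ppm\tr\tcovariance\tp_raw\tp_adj\tsignificant\n")
        for i in range(profile.ppm.size):
            fh.write(
                f"{profile.ppm[i]:.6f}\t{profile.r[i]:.10g}\t"
                f"{profile.covariance[i]:.10g}\t{profile.p_raw[i]:.6g}\t"
                f"{profile.p_adj[i]:.6g}\t{int(profile.significant[i])}\n"
            )
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    sc = ax.scatter(
        profile.ppm, profile.covariance, c=np.abs(profile.r), cmap="jet", s=2,
        vmin=0.0, vmax=1.0,
    )
    fig.colorbar(sc, ax=ax, label="|r|")
    ax.axvline(profile.driver, color="grey", lw=0.5, ls="--")
    ax.invert_xaxis()
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("covariance with driver")
    ax.set_title(f"STOCSY driver {profile.driver:.3f} ppm")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return tsv, png
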