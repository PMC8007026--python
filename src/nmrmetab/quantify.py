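"""Peak-area quantification and group statistics.

Window integration turns preprocessed spectra into relative concentrations
(trapezoidal area over each metabolite's assignment windows), which then
feed group summaries in the mean/SD/p-value/log2-fold-change layout used in
knockdown-versus-control metabolite tables, and a Spearman
metabolite-metabolite correlation matrix for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin

from .library import AssignmentTable
from .spectra import SpectrumSet

__all__ = [
    "ConcentrationTable",
    "integrate",
    "group_stats",
    "log2_fc_table",
    "spearman_matrix",
    "WindowIntegrator",
    "plot_correlation_heatmap",
]


@dataclass
class ConcentrationTable:
    """Samples x metabolites relative concentrations with group labels."""

    values: pd.DataFrame  # index = sample ids, columns = metabolites
    groups: pd.Series  # index = sample ids

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise ValueError("values and groups must share the sample index")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("concentrations must be finite")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)


def _window_indices(ppm: np.ndarray, windows) -> list[np.ndarray]:
    out = []
    for lo, hi in windows:
        idx = np.flatnonzero((ppm >= lo) & (ppm < hi))
        if idx.size < 2:
            raise ValueError(f"window [{lo}, {hi}) covers fewer than 2 axis points")
        out.append(idx)
    return out


def integrate(sset: SpectrumSet, assignment: AssignmentTable) -> ConcentrationTable:
    """Trapezoidal peak areas per sample and metabolite.

    Areas over a metabolite's windows are summed; negative intensities are
    integrated as-is (the baseline was already subtracted upstream).
    """
    X = sset.data.real.astype(float)
    ppm = sset.ppm
    cols = {}
    for name, windows in assignment.entries.items():
        idxs = _window_indices(ppm, windows)
        areas = np.zeros(sset.n_samples)
        for idx in idxs:
            areas += np.trapezoid(X[:, idx], ppm[idx], axis=1)
        cols[name] = areas
    ids = [s.sample_id for s in sset.samples]
    values = pd.DataFrame(cols, index=ids)
    groups = pd.Series(sset.groups(), index=ids, name="group")
    return ConcentrationTable(values, groups)


def group_stats(
    table: ConcentrationTable,
    control_label: str = "control",
    treated_label: str = "knockdown",
    test: str = "welch",
) -> pd.DataFrame:
    """Per-metabolite group means, SDs, two-sided t-test and log2 fold change.

    SDs use the n-1 denominator; the default test is Welch's (unequal
    variances), ``pooled`` selects the classical equal-variance t-test.
    Fold change is ``log2(treated_mean / control_mean)``, undefined (NaN,
    flagged) when the control mean is non-positive.
    """
    if test not in ("welch", "pooled"):
        raise ValueError(f"unknown test variant {test!r}")
    a = table.values[table.groups == control_label]
    b = table.values[table.groups == treated_label]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group for statistics")
    rows = []
    for name in table.metabolites:
        xa, xb = a[name].to_numpy(), b[name].to_numpy()
        ma, mb = float(xa.mean()), float(xb.mean())
        sa, sb = float(xa.std(ddof=1)), float(xb.std(ddof=1))
        if sa == 0.0 and sb == 0.0:
            p = 1.0 if ma == mb else 0.0
        else:
            p = float(
                scipy.stats.ttest_ind(xa, xb, equal_var=(test == "pooled")).pvalue
            )
        defined = ma > 0 and mb > 0
        lfc = float(np.log2(mb / ma)) if defined else float("nan")
        rows.append(
            {
                "metabolite": name,
                "control_mean": ma,
                "control_sd": sa,
                "treated_mean": mb,
                "treated_sd": sb,
                "p_value": p,
                "log2_fc": lfc,
                "fc_defined": defined,
            }
        )
    return pd.DataFrame(rows)


def log2_fc_table(stats: pd.DataFrame) -> pd.Series:
    """Signed log2 fold changes indexed by metabolite, in input order."""
    return pd.Series(
        stats["log2_fc"].to_numpy(), index=stats["metabolite"].to_numpy(), name="log2_fc"
    )


def spearman_matrix(table: ConcentrationTable) -> pd.DataFrame:
    """Spearman correlation between metabolite profiles across all samples.

    Ties get average ranks; constant metabolites yield NaN rows/columns
    (they carry no rank information) and are excluded from heatmap export.
    """
    if len(table.values) < 4:
        raise ValueError("need >= 4 samples for a correlation matrix")
    X = table.values.to_numpy()
    names = table.metabolites
    const = X.std(axis=0) == 0
    rho = table.values.corr(method="spearman").to_numpy()
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    return pd.DataFrame(rho, index=names, columns=names)


def plot_correlation_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the Spearman matrix as a heatmap PNG (NaN rows dropped)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keep = [c for c in matrix.columns if not matrix[c].isna().all()]
    m = matrix.loc[keep, keep]
    fig, ax = plt.subplots(figsize=(0.4 * len(keep) + 3, 0.4 * len(keep) + 2.5))
    im = ax.imshow(m.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(keep)), keep, rotation=90, fontsize=7)
    ax.set_yticks(range(len(keep)), keep, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


class WindowIntegrator(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper over :func:`integrate`: maps an
    (n_samples, n_points) matrix on a fixed ppm axis to an
    (n_samples, n_metabolites) area matrix; column order in
    ``metabolites_``."""

    def __init__(self, ppm, assignment: AssignmentTable):
        self.ppm = ppm
        self.assignment = assignment

    def fit(self, X=None, y=None):
        self.metabolites_ = list(self.assignment.entries)
        self.window_indices_ = {
            name: _window_indices(np.asarray(self.ppm), w)
            for name, w in self.assignment.entries.items()
        }
        return self

    def transform(self, X):
        if not hasattr(self, "window_indices_"):
            self.fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ppm = np.asarray(self.ppm)
        out = np.zeros((X.shape[0], len(self.metabolites_)))
        for j, name in enumerate(self.metabolites_):
            for idx in self.window_indices_[name]:
                out[:, j] += np.trapezoid(X[:, idx], ppm[idx], axis=1)
        return out
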