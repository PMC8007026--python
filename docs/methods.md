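# Methods

`nmrmetab` implements the analysis chain of a 1D ¹H-NMR cell-metabolomics
study comparing two sample groups (a gene-knockdown line against a control
line): spectral preprocessing, STOCSY-assisted identification, peak-area
quantification with group statistics, and pathway over-representation.
Because no raw spectra are publicly deposited for this kind of study, the
package carries a ground-truth-annotated spectrum simulator; every
quantitative claim the test suite makes is a recovery statement about
simulated data, scored against the simulator's recorded truth.

## Spectrum model and simulator

Spectra are generated directly in the frequency domain on a linear axis
covering −0.5 to 10.0 ppm (default 32768 points; the pipeline demo and the
fold-change benchmark use 16384 points — quantification bias grows
noticeably below ~1 point per half-linewidth — while the PQN and STOCSY
benchmarks use 8192, the smallest axis that still resolves the 1.2 Hz
default linewidth at 400 MHz).
Each metabolite contributes complex Lorentzian lines
`A(1 − iu)/(1 + u²)`, `u = (δ − δ₀)/w`, with half-width-at-half-maximum
`w = 1.2 Hz / 400 MHz = 0.003 ppm`. A metabolite at concentration *c* has
total absorption-mode area *c*, split equally across its multiplets and
within a multiplet by first-order rules (d 1:1, t 1:2:1, q 1:3:3:1; dd four
equal lines from a 4 + 10 Hz coupling pair; generic multiplets are five
equal lines over 0.04 ppm). Line spacing is J/field in ppm with a default
J of 7 Hz where the assignment tables print none — these defaults only
shape synthetic data, never the processing of real spectra.

Per sample the simulator adds, in order: a TSP reference singlet of fixed
height at 0 ppm (9-proton reference standard, deliberately *excluded* from
the dilution factor so that dilution correction and TSP referencing remain
distinguishable), a broad residual-water Lorentzian at 4.75 ppm (0.3 ppm
half-width, default height 200× TSP — large enough that the 4.5–5.0 ppm
exclusion demonstrably matters), multiplicative per-sample dilution
(log-uniform), zero- and first-order phase error applied in the complex
domain (`φ(x) = φ₀ + φ₁·x` with `x` the fractional axis position), a
degree-3 Chebyshev baseline on the real channel, global chemical-shift
jitter, and complex Gaussian noise. Randomness derives from
`default_rng([seed, sample_index])`, so adding a sample never perturbs
earlier samples.

Default study design (the conditions all recovery benchmarks use):
n = 5 per group; a 10-metabolite panel drawn from the intracellular
assignment table with base levels proportional to its printed control
means (acetate 0.667, alanine 0.884, citrate 0.659, cysteine 1.657,
formate 0.150, glutamate 2.893, lactate 3.895, succinate 0.983, uracil
0.032, valine 1.376 arbitrary units); knockdown effects cysteine −1.0 and
lactate +0.4 log2 units; biological CV 5 % (the tightest printed
replicate CVs are 1–4 %; the larger spreads in such tables are
between-experiment, n = 2 statistics); dilution 0.8–1.25; noise SD 1 % of
the TSP height; phase errors up to ±45°/±20°; baseline amplitude 2× TSP;
shift jitter SD 0.005 ppm. The panel deliberately omits metabolites whose
multiplets collide with the two effect metabolites (e.g. creatine's
3.04 ppm singlet under cysteine's 3.03 ppm doublet-of-doublets):
window integration cannot separate co-resonant signals, which is a
physical limit of binning-style quantification, not of the implementation.
The full 33-entry table remains available to the simulator and is what the
demo pipeline quantifies.

What the simulator does **not** emulate: J-coupling roofing and
second-order multiplet distortion, per-metabolite pH-dependent shift
changes (jitter is global), T₂ variation across peaks, radiation damping,
or FID-domain effects (apodization, zero-filling). Passing recovery tests
therefore show the pipeline is correct under idealized lineshapes and
artifact models, not that it handles every pathology of real spectra.

## Preprocessing

Order: phase → baseline → TSP referencing → trimming → PQN. Trimming
before PQN (the alternative order is defensible; trimming first keeps the
enormous residual-water intensity out of the quotient statistics).

**Phasing.** Two stages. A coarse grid (10° steps over φ₀ ∈ [−180, 180),
φ₁ ∈ [−60, 60]) minimizes a *detrended* negativity penalty: squared
negative intensity after subtracting an interpolated per-segment
10th-percentile floor (16 segments). The floor makes the penalty respond
to the narrow negative dispersion lobes of mis-phased peaks rather than to
baseline drift or the water hump's tails — plain negativity fails here
because the water tail is a positive pedestal that hides the lobes. The
coarse optimum is then refined by fitting, at up to 30 strong narrow
peaks, a complex Lorentzian plus local linear complex baseline in a tight
window; the fitted phase parameter measures the residual local phase, and
a robust (outlier-rejecting) weighted line through local phase versus
axis position separates φ₀ from φ₁ — a split the negativity penalty
leaves nearly degenerate when strong peaks cluster in one spectral region.
Fits that come back broad or off-centre (the water plateau) are rejected.
On artifact-free spectra the recovery error is below 1°; under the full
default artifact model it stays below ~4°, i.e. peak-area distortion
below 0.3 %.

**Baseline.** Asymmetric least squares (Whittaker smoother with asymmetry
p = 0.001 and smoothness λ = 10⁷ in point-index units, 10 reweighting
iterations), solved per spectrum with a symmetric banded Cholesky solve.
λ = 10⁷ corresponds to a ~0.02–0.04 ppm flexibility scale at the default
resolutions — stiff enough not to eat Lorentzian peaks, flexible enough to
follow the Chebyshev drift and the water tails. Baseline + corrected
spectrum reconstructs the input exactly.

**TSP referencing.** The apex of the strongest peak within ±0.3 ppm of
0 ppm is located by parabolic interpolation over the apex triplet and the
axis shifted so it sits at exactly 0 ppm (linear resampling). A peak is
required to exceed 5× a noise estimate (scaled median absolute successive
difference), otherwise "TSP not found".

**Trimming.** Keep [0.6, 9.0) ppm, remove [4.5, 5.0); all interval tests
are half-open `[lo, hi)`.

**PQN.** (1) scale each spectrum to unit total (summed) intensity;
(2) reference = point-wise median of the control-group spectra (a single
designated sample may be substituted); (3) per-sample factor = median of
point-wise sample/reference quotients over points where the reference
exceeds its 5th percentile (division-by-noise guard); (4) divide. The
reported factor is the product of both scalings, so it estimates the
sample's overall dilution; re-running PQN on its own output returns unit
factors. With the reference standard excluded from dilution and the TSP
region trimmed away, recovered factors track true dilutions to better
than 1 % (median) with Pearson r > 0.99 over a 0.5–2× dilution range.

## STOCSY

Pearson correlation (Spearman optional) of the driver point — snapped to
the nearest axis point, ties to the lower ppm — against all retained
points across samples, with the matching covariance trace. Two-sided
p-values from `t = r√(n−2)/√(1−r²)` on n−2 df; the driver point is exact
(r = 1, p = 0). Adjustment is Bonferroni by default — the procedure the
source protocol names — with Benjamini–Hochberg step-up available; the
"Bonferroni FDR" phrasing in such protocols conflates FWER and FDR
control, so both are exposed. A point is significant when the adjusted p
falls below α = 0.05 *and* |r| ≥ 0.8; the r-threshold default is a package
choice (the protocol calculates but does not print one). The reported
false-positive ratio is α·m / max(1, #significant). The pseudo-2D export
writes covariance coloured by |r| plus a TSV of the full profile.

## Quantification and statistics

Integration windows are ± half-width (default 0.02 ppm) around each
multiplet centre, merged per metabolite, clipped to the retained region,
and forbidden from overlapping the water band or the TSP band
[−0.1, 0.1] ppm (the assignment tables contain one 0 ppm entry that would
otherwise collide with the reference). Areas are trapezoidal, negative
points included as-is since the baseline is already subtracted.
Group statistics per metabolite: means, n−1 SDs, two-sided t-test (Welch
default — the source protocol says only "t-test", and its printed
p-values cannot be reconciled with either variant at any plausible n, so
best practice decides), and log2 fold change of group means (undefined
and flagged when a mean is non-positive). The Spearman matrix correlates
metabolite concentration profiles across all samples pooled (a per-group
restriction is available); constant metabolites are marked undefined and
dropped from the heatmap.

## Over-representation analysis

Hypergeometric upper tail P(X ≥ k) for k matched query compounds in a
pathway of n compounds, query size K (after intersecting with the
universe), universe N, accumulated in log space (gammaln + logsumexp).
Only pathways with k ≥ 1 are tested and the adjustment multiplicity is
the number of tested pathways; default adjustment is Benjamini–Hochberg,
matching the FDR-like "adjusted p-value" column of MBRole-style reports.
The packaged pathway fixture reproduces the combinatorial shape of such a
report — 19 pathways whose background sizes match the published table,
universe 1455 (its largest background) — with synthetic memberships and
compound ids; published enrichment p-values depend on the database
snapshot behind the original web service and are deliberately not
reproduction targets. The co-membership network links query compounds
sharing ≥ 1 pathway (weight = shared count, direction-of-change node
annotations from log2 fold changes); it stands in for the curated
metabolite–metabolite interaction networks of such services, which are
out of scope.

## Numerical notes

- A Lorentzian's area is πAw, but a window of ±10 half-widths captures
  only (2/π)·arctan(10) ≈ 93.7 % of it; the integration oracle therefore
  uses a 200-half-width window (99.4 % capture, within the 1 % check).
  For relative concentrations the truncation cancels in fold-change
  ratios, which is why narrow windows are safe downstream.
- Hypergeometric correctness is swept exhaustively for every valid
  instance with N ≤ 25 against exact rational arithmetic, plus a literal
  subset-enumeration oracle for N ≤ 8 and a scipy cross-check at larger N.
- Zero-variance conventions: identical groups give p = 1; constant
  metabolites give undefined Spearman rows; a zero-variance STOCSY driver
  is an error.
- Determinism: one config seed drives everything; per-sample substreams
  are keyed `[seed, sample_index]`; reruns are byte-identical for all
  numeric TSV outputs.

## Known limitations

Window integration cannot deconvolve co-resonant metabolites (see panel
note above); the global shift model cannot represent per-metabolite pH
shifts, so real spectra with strong positional drift would need
segment-wise alignment (out of scope); enrichment results are only as
meaningful as the supplied pathway database; and the phase-recovery
guarantee is stated for the simulator's artifact model, not for spectra
with strong out-of-model distortions.
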