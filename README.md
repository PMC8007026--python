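# nmrmetab

A reproducible pipeline for 1D ¹H-NMR cell metabolomics of two-group
(knockdown vs control) studies: spectral preprocessing, STOCSY-assisted
metabolite identification, peak-area quantification with group statistics,
and pathway over-representation analysis — plus a ground-truth-annotated
synthetic-spectrum generator so that every stage can be validated against
known answers.

It is aimed at analysts who have (or want to emulate) 400 MHz 1D spectra
of cell extracts or conditioned media and need a scripted, seeded
alternative to interactive processing: the kind of study that asks "which
metabolites change when this gene is silenced, and which pathways do they
implicate?"

## What it computes

- **Preprocessing** (`nmrmetab.preprocess`): automatic zero/first-order
  phasing (detrended-negativity grid search + per-peak complex Lorentzian
  refinement), asymmetric-least-squares baseline removal, TSP referencing
  to δ = 0, trimming to 0.6–9.0 ppm with the 4.5–5.0 ppm water band
  removed, and probabilistic quotient normalization (PQN) against the
  control-group median spectrum. Each step is also exposed as a
  scikit-learn transformer (`PhaseCorrector`, `BaselineCorrector`,
  `TspReferencer`, `RegionTrimmer`, `PqnNormalizer`) that composes with
  `sklearn.pipeline.Pipeline`.
- **STOCSY** (`nmrmetab.stocsy`): correlation/covariance profile of a
  driver chemical shift against all retained points, t-distribution
  p-values with Bonferroni (default) or Benjamini–Hochberg adjustment,
  pseudo-2D export.
- **Quantification** (`nmrmetab.quantify`): trapezoidal window
  integration driven by the packaged multiplet assignment tables
  (33 intracellular and 25 extracellular metabolites), group mean/SD,
  Welch or pooled t-tests, log2 fold changes, Spearman
  metabolite–metabolite correlation heatmaps.
- **Enrichment** (`nmrmetab.enrichment`): log-space hypergeometric
  over-representation against a pathway database (packaged synthetic
  fixture with a 1455-compound universe, or any user-supplied table) and
  a pathway co-membership network.
- **Simulation** (`nmrmetab.simulate`): seeded two-group spectrum sets
  with Lorentzian multiplets, TSP and residual-water signals, dilution,
  phase/baseline/shift artifacts and noise, with full per-sample ground
  truth recorded.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Run the bundled knockdown-vs-control demo (5 + 5 samples, 10-metabolite
panel, cysteine −1.0 / lactate +0.4 log2 effects, full artifact model):

```bash
nmrmetab demo --outdir demo_out --seed 1
```

which finishes in well under a minute and reports

```
demo complete; outputs in demo_out
{
 "enrich":     {"pathways_tested": 11, "query_size": 12, "significant": 4},
 "library":    {"entries": 33, "windows": 119},
 "preprocess": {"retained_points": 12326},
 "quantify":   {"metabolites": 33, "significant": 12},
 "simulate":   {"points": 16384, "samples": 10},
 "stocsy":     {"drivers": [1.33], "files": ["demo_out/stocsy_1p330.tsv"]}
}
```

`demo_out/group_stats.tsv` then contains one row per metabolite in the
published-table layout; for the two metabolites with injected effects the
seed-1 run estimates

| metabolite | true log2 FC | estimated log2 FC | p (Welch) |
|------------|--------------|-------------------|-----------|
| Cysteine   | −1.0         | −0.98             | 5e-9      |
| Lactate    | +0.4         | +0.41             | 6e-6      |

i.e. the full chain (phasing through PQN to integration) recovers the
injected effects to within a few hundredths of a log2 unit, while the
null metabolites sit near 0. `spearman.tsv`/`spearman_heatmap.png` hold
the metabolite correlation matrix, `stocsy_1p330.tsv` the lactate-driver
STOCSY profile, and `enrichment.tsv` the pathway table (ID, Pathway,
p-value, Adjusted p-value, In background, In set).

The same chain is scriptable from Python:

```python
import nmrmetab as nm

lib = nm.load_library(nm.packaged_library_path("intracellular"), "intracellular")
design = nm.StudyDesign(seed=1)                     # defaults documented in docs/methods.md
raw = nm.simulate_spectrum_set(design, lib, n_points=16384)
proc, report = nm.preprocess_spectrum_set(raw)
conc = nm.integrate(proc, nm.build_assignment_windows(lib))
stats = nm.group_stats(conc)                        # means, SDs, p, log2 FC
profile = nm.stocsy_profile(proc, driver_ppm=1.33)  # lactate CH3 driver
```

Other CLI subcommands (`simulate`, `preprocess`, `stocsy`, `quantify`,
`enrich`, `run`) operate on files; `nmrmetab run --config cfg.yaml
--outdir out` drives the whole chain from one YAML document, and user
spectra can be supplied as a ppm/intensity TSV + JSON sidecar in place of
the simulator.

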