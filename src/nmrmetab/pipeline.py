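"""Configuration-driven orchestration of the full analysis chain.

One YAML document describes a run: simulate (or load) spectra, preprocess,
STOCSY, quantify, and pathway enrichment.  All randomness flows from the
single config seed; re-running an identical config reproduces every numeric
output byte for byte.
"""

from __future__ import annotations

import json
import logging
from copy import deepcopy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .enrichment import cooccurrence_network, enrich, enrichment_table
from .library import (
    build_assignment_windows,
    load_library,
    load_pathway_db,
    packaged_library_path,
)
from .preprocess import preprocess_spectrum_set
from .quantify import (
    group_stats,
    integrate,
    log2_fc_table,
    plot_correlation_heatmap,
    spearman_matrix,
)
from .simulate import StudyDesign, simulate_spectrum_set
from .spectra import read_spectrum_set, write_spectrum_set
from .stocsy import export_pseudo2d, stocsy_profile

__all__ = ["PipelineConfig", "ConfigError", "PipelineStageError", "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)

_DEFAULTS: dict = {
    "seed": 0,
    "input": None,  # external spectrum-set prefix; overrides 'simulate'
    "library": "intracellular",
    "half_width": 0.02,
    "simulate": {
        "n_control": 5,
        "n_knockdown": 5,
        "base_concentrations": None,  # None -> default panel
        "log2_effects": None,  # None -> default effects
        "biological_cv": 0.05,
        "dilution_range": [0.8, 1.25],
        "noise_sd": 0.01,
        "phase0_range": 45.0,
        "phase1_range": 20.0,
        "baseline_amplitude": 2.0,
        "shift_jitter_sd": 0.005,
        "n_points": 16384,
    },
    "preprocess": {
        "keep": [0.6, 9.0],
        "drop": [[4.5, 5.0]],
        "pqn_reference": "control",
    },
    "stocsy": {
        "drivers": [1.33],
        "alpha": 0.05,
        "method": "bonferroni",
        "threshold_r": 0.8,
    },
    "stats": {
        "test": "welch",
        "control_label": "control",
        "treated_label": "knockdown",
    },
    "enrichment": {
        "enabled": True,
        "method": "bh",
        "max_p": 0.05,
        "pathway_db": None,  # None -> packaged fixture
    },
}


class ConfigError(ValueError):
    """All schema violations of a config file, collected."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    raw: dict = field(default_factory=lambda: deepcopy(_DEFAULTS))

    def __getitem__(self, key):
        return self.raw[key]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=False)


def _merge_defaults(user: dict, defaults: dict) -> dict:
    out = deepcopy(defaults)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge_defaults(val, out[key])
        else:
            out[key] = val
    return out


def _check(cfg: dict) -> list[str]:
    errors: list[str] = []

    def interval(val, name, half_open=True):
        if (
            not isinstance(val, (list, tuple))
            or len(val) != 2
            or not all(isinstance(v, (int, float)) for v in val)
            or not val[0] < val[1]
        ):
            errors.append(f"{name}: expected an increasing [lo, hi] pair, got {val!r}")

    unknown = set(cfg) - set(_DEFAULTS)
    if unknown:
        errors.append(f"unknown top-level keys: {sorted(unknown)}")
    if not isinstance(cfg.get("seed"), int):
        errors.append("seed: must be an integer")
    if cfg.get("library") not in ("intracellular", "extracellular"):
        errors.append(f"library: must be intracellular or extracellular, got {cfg.get('library')!r}")
    hw = cfg.get("half_width")
    if not isinstance(hw, (int, float)) or hw <= 0:
        errors.append(f"half_width: must be > 0, got {hw!r}")
    sim = cfg.get("simulate", {})
    for key in ("n_control", "n_knockdown"):
        if not isinstance(sim.get(key), int) or sim.get(key, 0) < 2:
            errors.append(f"simulate.{key}: must be an integer >= 2")
    if not isinstance(sim.get("n_points"), int) or sim["n_points"] < 4096:
        errors.append("simulate.n_points: must be an integer >= 4096")
    interval(sim.get("dilution_range"), "simulate.dilution_range")
    pre = cfg.get("preprocess", {})
    interval(pre.get("keep"), "preprocess.keep")
    for i, d in enumerate(pre.get("drop") or []):
        interval(d, f"preprocess.drop[{i}]")
    sto = cfg.get("stocsy", {})
    if not isinstance(sto.get("drivers"), list) or not sto["drivers"]:
        errors.append("stocsy.drivers: must be a non-empty list of ppm values")
    if sto.get("method") not in ("bonferroni", "bh"):
        errors.append(f"stocsy.method: bonferroni or bh, got {sto.get('method')!r}")
    if cfg.get("stats", {}).get("test") not in ("welch", "pooled"):
        errors.append(f"stats.test: welch or pooled, got {cfg.get('stats', {}).get('test')!r}")
    if cfg.get("enrichment", {}).get("method") not in ("bonferroni", "bh"):
        errors.append("enrichment.method: bonferroni or bh")
    inp = cfg.get("input")
    if inp is not None and not Path(inp).with_suffix(".tsv").exists():
        errors.append(f"input: spectrum set {inp!r} not found")
    db = cfg.get("enrichment", {}).get("pathway_db")
    if db is not None and not Path(db).exists():
        errors.append(f"enrichment.pathway_db: {db!r} not found")
    return errors


def validate_config(path_or_dict: str | Path | dict) -> PipelineConfig:
    """Parse, default-fill and validate a config; all violations reported
    together.  Validation is idempotent: a filled config re-validates to
    itself."""
    if isinstance(path_or_dict, dict):
        user = deepcopy(path_or_dict)
    else:
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path_or_dict}: config must be a mapping")
    cfg = _merge_defaults(user, _DEFAULTS)
    errors = _check(cfg)
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return PipelineConfig(cfg)


def _tsv_header(seed: int) -> str:
    return f"# nmrmetab {__version__} seed={seed}\n"


def _write_df(df, path: Path, seed: int, index=True) -> None:
    with path.open("w") as fh:
        fh.write(_tsv_header(seed))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, output_dir: str | Path) -> dict:
    """Execute the enabled stages in order and write the output bundle.

    Returns the run manifest (also written to ``run.json``).  Any stage
    error is re-raised as :class:`PipelineStageError` naming the stage.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.raw
    seed = cfg["seed"]
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("nmrmetab")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    manifest: dict = {"package": "nmrmetab", "version": __version__, "seed": seed,
                      "config": deepcopy(cfg), "stages": {}}
    try:
        # ---------------- library
        stage = "library"
        library = load_library(packaged_library_path(cfg["library"]), cfg["library"])
        windows = build_assignment_windows(library, half_width=cfg["half_width"])
        manifest["stages"][stage] = {"entries": len(library), "windows": windows.window_count()}

        # ---------------- spectra
        if cfg["input"] is not None:
            stage = "load"
            sset = read_spectrum_set(cfg["input"])
        else:
            stage = "simulate"
            sim = cfg["simulate"]
            design_kw = dict(
                n_control=sim["n_control"],
                n_knockdown=sim["n_knockdown"],
                biological_cv=sim["biological_cv"],
                dilution_range=tuple(sim["dilution_range"]),
                noise_sd=sim["noise_sd"],
                phase0_range=sim["phase0_range"],
                phase1_range=sim["phase1_range"],
                baseline_amplitude=sim["baseline_amplitude"],
                shift_jitter_sd=sim["shift_jitter_sd"],
                seed=seed,
            )
            if sim["base_concentrations"]:
                design_kw["base_concentrations"] = dict(sim["base_concentrations"])
            if sim["log2_effects"] is not None:
                design_kw["log2_effects"] = dict(sim["log2_effects"])
            design = StudyDesign(**design_kw)
            sset = simulate_spectrum_set(design, library, n_points=sim["n_points"])
            write_spectrum_set(sset, outdir / "raw_spectra")
        manifest["stages"][stage] = {"samples": sset.n_samples, "points": int(sset.ppm.size)}

        # ---------------- preprocess
        stage = "preprocess"
        pre = cfg["preprocess"]
        proc, report = preprocess_spectrum_set(
            sset,
            keep=tuple(pre["keep"]),
            drop=tuple(tuple(d) for d in (pre["drop"] or [])),
            pqn_reference_group=pre["pqn_reference"],
        )
        write_spectrum_set(proc, outdir / "preprocessed_spectra")
        rep = report.to_dict()
        rep["package_version"] = __version__
        rep["seed"] = seed
        (outdir / "preprocessing_report.json").write_text(json.dumps(rep, indent=1))
        manifest["stages"][stage] = {"retained_points": int(proc.ppm.size)}

        # ---------------- stocsy
        stage = "stocsy"
        sto = cfg["stocsy"]
        stocsy_files = []
        for driver in sto["drivers"]:
            profile = stocsy_profile(
                proc,
                driver_ppm=float(driver),
                alpha=sto["alpha"],
                threshold_r=sto["threshold_r"],
                method=sto["method"],
            )
            tsv, png = export_pseudo2d(
                profile,
                outdir / f"stocsy_{float(driver):.3f}".replace(".", "p", 1),
                header_comment=f"nmrmetab {__version__} seed={seed}",
            )
            stocsy_files.append(str(tsv))
        manifest["stages"][stage] = {"drivers": [float(d) for d in sto["drivers"]],
                                     "files": stocsy_files}

        # ---------------- quantify
        stage = "quantify"
        st = cfg["stats"]
        conc = integrate(proc, windows)
        stats = group_stats(
            conc,
            control_label=st["control_label"],
            treated_label=st["treated_label"],
            test=st["test"],
        )
        rho = spearman_matrix(conc)
        _write_df(conc.values, outdir / "concentrations.tsv", seed)
        _write_df(stats, outdir / "group_stats.tsv", seed, index=False)
        _write_df(rho, outdir / "spearman.tsv", seed)
        plot_correlation_heatmap(rho, outdir / "spearman_heatmap.png")
        manifest["stages"][stage] = {
            "metabolites": len(conc.metabolites),
            "significant": int((stats["p_value"] < 0.05).sum()),
        }

        # ---------------- enrichment
        if cfg["enrichment"]["enabled"]:
            stage = "enrich"
            en = cfg["enrichment"]
            db_path = en["pathway_db"] or packaged_library_path("pathways")
            db = load_pathway_db(db_path)
            by_name = {e.name: e.compound_id for e in library}
            sig = stats[stats["p_value"] < en["max_p"]]
            chosen = sig if len(sig) else stats
            query = {by_name[m] for m in chosen["metabolite"]}
            lfc = {
                by_name[m]: f
                for m, f in log2_fc_table(chosen).items()
                if np.isfinite(f)
            }
            rows = enrich(query, db, method=en["method"])
            _write_df(enrichment_table(rows), outdir / "enrichment.tsv", seed, index=False)
            net = cooccurrence_network(query, db, log2_fc=lfc)
            import networkx as nx

            nx.write_graphml(net, outdir / "network.graphml")
            with (outdir / "network_edges.tsv").open("w") as f:
                f.write(_tsv_header(seed))
                f.write("source\ttarget\tshared_pathways\n")
                for a, b, d in net.edges(data=True):
                    f.write(f"{a}\t{b}\t{d['weight']}\n")
            manifest["stages"][stage] = {
                "query_size": len(query),
                "pathways_tested": len(rows),
                "significant": int(sum(r.adjusted_p < 0.05 for r in rows)),
            }

        (outdir / "run.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    finally:
        root.removeHandler(fh)
        fh.close()
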