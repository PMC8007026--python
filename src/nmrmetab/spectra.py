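"""The ``SpectrumSet`` container: a shared ppm axis plus per-sample spectra.

Spectra are stored frequency-domain; before phase correction they are
complex-valued (absorption + i*dispersion), afterwards real.  Serialization
is one TSV (axis + one column per sample, real or re/im column pairs) plus a
JSON sidecar holding sample metadata and, for synthetic sets, the simulation
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["SampleMeta", "SpectrumSet", "write_spectrum_set", "read_spectrum_set", "SpectrumFormatError"]


class SpectrumFormatError(ValueError):
    """Raised when a serialized spectrum set cannot be read back."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str


@dataclass
class SpectrumSet:
    """Aligned 1D spectra: ``data[i]`` is sample ``samples[i]`` on ``ppm``."""

    ppm: np.ndarray  # strictly increasing, shape (n_points,)
    data: np.ndarray  # shape (n_samples, n_points), float or complex
    samples: list[SampleMeta]
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.ppm.ndim != 1 or np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm axis must be 1-D and strictly increasing")
        if self.data.shape != (len(self.samples), self.ppm.size):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.samples)} samples x {self.ppm.size} points"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.data)

    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.samples])

    def group_index(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.groups() == group)

    def copy_with(self, **kw) -> "SpectrumSet":
        out = replace(self, **kw)
        return out


def write_spectrum_set(sset: SpectrumSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` + ``<prefix>.json``; values at full precision."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    sidecar = prefix.with_suffix(".json")
    cols = ["ppm"]
    mats = [sset.ppm]
    for i, meta in enumerate(sset.samples):
        if sset.is_complex:
            cols += [f"{meta.sample_id}_re", f"{meta.sample_id}_im"]
            mats += [sset.data[i].real, sset.data[i].imag]
        else:
            cols.append(meta.sample_id)
            mats.append(sset.data[i].real)
    arr = np.column_stack(mats)
    with tsv.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, arr, fmt="%.17g", delimiter="\t")
    meta = {
        "format": "nmrmetab-spectrum-set-v1",
        "complex": bool(sset.is_complex),
        "samples": [{"sample_id": s.sample_id, "group": s.group} for s in sset.samples],
        "truth": sset.truth,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return tsv, sidecar


def read_spectrum_set(prefix: str | Path) -> SpectrumSet:
    """Read a spectrum set written by :func:`write_spectrum_set`."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    sidecar = prefix.with_suffix(".json")
    try:
        meta = json.loads(sidecar.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SpectrumFormatError(f"cannot read sidecar {sidecar}: {exc}") from exc
    if meta.get("format") != "nmrmetab-spectrum-set-v1":
        raise SpectrumFormatError(f"{sidecar}: unknown format tag {meta.get('format')!r}")
    try:
        with tsv.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            arr = np.loadtxt(fh, delimiter="\t", ndmin=2)
    except (OSError, ValueError) as exc:
        raise SpectrumFormatError(f"cannot read {tsv}: {exc}") from exc
    samples = [SampleMeta(s["sample_id"], s["group"]) for s in meta["samples"]]
    expected = 1 + (2 if meta["complex"] else 1) * len(samples)
    if len(header) != expected or arr.shape[1] != expected:
        raise SpectrumFormatError(
            f"{tsv}: expected {expected} columns, found {arr.shape[1]}"
        )
    ppm = arr[:, 0]
    if meta["complex"]:
        data = np.empty((len(samples), ppm.size), dtype=complex)
        for i, s in enumerate(samples):
            if header[1 + 2 * i] != f"{s.sample_id}_re":
                raise SpectrumFormatError(f"{tsv}: column/sample mismatch at {s.sample_id}")
            data[i] = arr[:, 1 + 2 * i] + 1j * arr[:, 2 + 2 * i]
    else:
        data = np.empty((len(samples), ppm.size), dtype=float)
        for i, s in enumerate(samples):
            if header[1 + i] != s.sample_id:
                raise SpectrumFormatError(f"{tsv}: column/sample mismatch at {s.sample_id}")
            data[i] = arr[:, 1 + i]
    return SpectrumSet(ppm, data, samples, truth=meta.get("truth"))
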