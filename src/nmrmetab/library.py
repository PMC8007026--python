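"""Metabolite assignment library and pathway fixtures.

The package ships two assignment tables (intracellular cell-extract and
extracellular conditioned-medium metabolites) listing each metabolite's
1H multiplets as ``shift(code)`` tokens, plus a pathway-annotation table
used by the over-representation module.  This module parses and validates
those tables and derives peak-integration windows from the multiplet
positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "MultipletSignal",
    "LibraryEntry",
    "AssignmentTable",
    "PathwayDB",
    "LibraryError",
    "load_library",
    "packaged_library_path",
    "build_assignment_windows",
    "load_pathway_db",
    "write_pathway_db",
]

log = logging.getLogger(__name__)

#: Retained chemical-shift region after standard trimming (ppm, half-open).
KEEP_REGION = (0.6, 9.0)
#: Residual-water exclusion band (ppm, half-open).
WATER_BAND = (4.5, 5.0)
#: Reference (TSP) exclusion band: no integration window may overlap it.
TSP_BAND = (-0.1, 0.1)

MULTIPLICITY_CODES = ("s", "d", "t", "q", "dd", "m")

#: Default scalar couplings in Hz when the assignment table prints none:
#: 7 Hz for d/t/q, a 4 + 10 Hz pair for dd.  Generic multiplets (m) are
#: modelled as N_LINES_M equally spaced lines over M_SPAN_PPM.
DEFAULT_J = {"d": (7.0,), "t": (7.0,), "q": (7.0,), "dd": (4.0, 10.0)}
N_LINES_M = 5
M_SPAN_PPM = 0.04

# printed two-letter combination codes folded into the generic multiplet code
_CODE_ALIASES = {"S": "s", "td": "m", "dq": "m", "dt": "m", "qd": "m"}

_TOKEN_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*\(\s*([A-Za-z]+)\s*\)\s*$")


class LibraryError(ValueError):
    """Raised for malformed or inconsistent fixture content."""


@dataclass(frozen=True)
class MultipletSignal:
    """One multiplet: centre shift (ppm), multiplicity code, couplings."""

    center: float
    multiplicity: str
    j_coupling: tuple[float, ...] | None = None
    n_lines: int | None = None

    def __post_init__(self) -> None:
        if not (-0.5 <= self.center <= 10.0):
            raise LibraryError(
                f"multiplet centre {self.center} ppm outside [-0.5, 10.0]"
            )
        if self.multiplicity not in MULTIPLICITY_CODES:
            raise LibraryError(f"unknown multiplicity code {self.multiplicity!r}")
        if self.j_coupling is not None and any(j <= 0 for j in self.j_coupling):
            raise LibraryError("j_coupling must be positive")
        if self.multiplicity == "m" and (self.n_lines is None or self.n_lines < 1):
            raise LibraryError("multiplet (m) requires positive n_lines")


@dataclass(frozen=True)
class LibraryEntry:
    """A metabolite with its ordered multiplet list."""

    name: str
    compound_id: str
    compartment: str
    multiplets: tuple[MultipletSignal, ...]

    def __post_init__(self) -> None:
        if self.compartment not in ("intracellular", "extracellular", "both"):
            raise LibraryError(f"bad compartment {self.compartment!r}")
        if not self.multiplets:
            raise LibraryError(f"{self.name}: at least one multiplet required")


@dataclass
class AssignmentTable:
    """Per-metabolite integration windows as half-open ppm intervals."""

    entries: dict[str, list[tuple[float, float]]]
    half_width: float

    def window_count(self) -> int:
        return sum(len(v) for v in self.entries.values())


@dataclass
class PathwayDB:
    """Compound-to-pathway map with an explicit background universe."""

    pathways: dict[str, dict]  # id -> {"name": str, "compounds": frozenset}
    universe: frozenset[str]
    source_label: str = ""

    def __post_init__(self) -> None:
        for pid, rec in self.pathways.items():
            if not rec["compounds"]:
                raise LibraryError(f"pathway {pid} has an empty compound set")
            extra = rec["compounds"] - self.universe
            if extra:
                raise LibraryError(
                    f"pathway {pid} references compounds outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def _parse_multiplet_token(token: str, row: str) -> MultipletSignal:
    match = _TOKEN_RE.match(token)
    if match is None:
        raise LibraryError(f"row {row!r}: cannot parse multiplet token {token!r}")
    center = float(match.group(1))
    code = match.group(2)
    code = _CODE_ALIASES.get(code, code)
    if code not in MULTIPLICITY_CODES:
        raise LibraryError(f"row {row!r}: malformed multiplicity code {match.group(2)!r}")
    if code == "m":
        return MultipletSignal(center, "m", None, N_LINES_M)
    return MultipletSignal(center, code, DEFAULT_J.get(code))


def parse_multiplet_string(text: str, row: str = "?") -> tuple[MultipletSignal, ...]:
    """Parse a printed multiplet list such as ``"1.91(s); 1.92(s)"``."""
    tokens = [t for t in text.split(";") if t.strip()]
    if not tokens:
        raise LibraryError(f"row {row!r}: empty multiplet list")
    return tuple(_parse_multiplet_token(t, row) for t in tokens)


def packaged_library_path(which: str) -> Path:
    """Path of a packaged fixture: 'intracellular', 'extracellular' or 'pathways'."""
    names = {
        "intracellular": "intracellular_library.tsv",
        "extracellular": "extracellular_library.tsv",
        "pathways": "pathways.tsv",
    }
    if which not in names:
        raise ValueError(f"unknown fixture {which!r}")
    return Path(str(resources.files("nmrmetab").joinpath("data", names[which])))


def load_library(path: str | Path, compartment: str) -> list[LibraryEntry]:
    """Load and validate a metabolite assignment table.

    The file is tab-separated with columns ``name``, ``compound_id``,
    ``multiplets``; ``#`` lines are comments and the first non-comment row is
    the header.
    """
    path = Path(path)
    lines = [
        ln
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise LibraryError(f"{path}: empty assignment table")
    header = lines[0].split("\t")
    if header[:3] != ["name", "compound_id", "multiplets"]:
        raise LibraryError(f"{path}: unexpected header {header!r}")
    entries: list[LibraryEntry] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise LibraryError(f"{path}: malformed row {ln!r}")
        name, cid, mults = (p.strip() for p in parts)
        if name in seen:
            raise LibraryError(f"{path}: duplicate metabolite name {name!r}")
        seen.add(name)
        entries.append(
            LibraryEntry(name, cid, compartment, parse_multiplet_string(mults, name))
        )
    return entries


def _merge_intervals(
    intervals: Iterable[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Union of half-open intervals; touching intervals are merged."""
    out: list[tuple[float, float]] = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _clip(interval, keep, drops):
    """Clip one interval to keep-region minus drop bands; may split/vanish."""
    lo = max(interval[0], keep[0])
    hi = min(interval[1], keep[1])
    pieces = [(lo, hi)] if lo < hi else []
    for dlo, dhi in drops:
        nxt = []
        for plo, phi in pieces:
            if phi <= dlo or plo >= dhi:
                nxt.append((plo, phi))
            else:
                if plo < dlo:
                    nxt.append((plo, dlo))
                if phi > dhi:
                    nxt.append((dhi, phi))
        pieces = nxt
    return pieces


def build_assignment_windows(
    library: list[LibraryEntry], half_width: float = 0.02
) -> AssignmentTable:
    """Derive integration windows ``[centre - hw, centre + hw)`` per metabolite.

    Windows are merged per metabolite, clipped to the retained region, and any
    window overlapping the water band or the TSP reference band is cut back or
    dropped (quantification must not touch either region).
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    table: dict[str, list[tuple[float, float]]] = {}
    missing: list[str] = []
    drops = [WATER_BAND, TSP_BAND]
    for entry in library:
        raw = [
            (m.center - half_width, m.center + half_width) for m in entry.multiplets
        ]
        clipped: list[tuple[float, float]] = []
        for iv in raw:
            pieces = _clip(iv, KEEP_REGION, drops)
            if not pieces:
                log.warning(
                    "%s: multiplet window %.3f-%.3f ppm entirely in an excluded "
                    "region; dropped",
                    entry.name,
                    *iv,
                )
            clipped.extend(pieces)
        merged = _merge_intervals(clipped)
        if not merged:
            missing.append(entry.name)
        else:
            table[entry.name] = merged
    if missing:
        raise LibraryError(
            f"metabolites with no integration window in the retained region: {missing}"
        )
    return AssignmentTable(table, half_width)


def load_pathway_db(path: str | Path) -> PathwayDB:
    """Load a pathway-annotation TSV (see the packaged ``pathways.tsv``)."""
    path = Path(path)
    lines = [
        ln
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines or lines[0].split("\t")[:3] != ["pathway_id", "name", "compounds"]:
        raise LibraryError(f"{path}: missing pathway table header")
    universe: frozenset[str] | None = None
    pathways: dict[str, dict] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise LibraryError(f"{path}: malformed row {ln!r}")
        pid, name, compounds = parts
        ids = [c for c in compounds.split(";") if c]
        if pid == "_universe_":
            universe = frozenset(ids)
        else:
            if pid in pathways:
                raise LibraryError(f"{path}: duplicate pathway id {pid!r}")
            pathways[pid] = {"name": name, "compounds": frozenset(ids)}
    if universe is None:
        raise LibraryError(f"{path}: no '_universe_' row")
    return PathwayDB(pathways, universe, source_label=str(path))


def write_pathway_db(db: PathwayDB, path: str | Path) -> None:
    """Serialize a PathwayDB in the fixture TSV dialect (read/write round-trips)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("pathway_id\tname\tcompounds\n")
        fh.write("_universe_\tbackground universe\t" + ";".join(sorted(db.universe)) + "\n")
        for pid in sorted(db.pathways):
            rec = db.pathways[pid]
            fh.write(f"{pid}\t{rec['name']}\t" + ";".join(sorted(rec["compounds"])) + "\n")
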