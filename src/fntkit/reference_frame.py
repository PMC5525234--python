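"""Reference coordinate frame for the FNT family.

All positional analysis in this package is expressed in the residue numbering
of the *E. coli* FocA crystal structure (PDB 3KCU), which serves the FNT
family as a common coordinate system: ten secondary-structure segments (six
transmembrane helices, with TM2 and TM5 split into a/b halves by the Ω- and
S-loops) and the two pore constrictions — the central constriction
(positions 75, 202, 209, 212; canonically F, F, H, A) and the cytoplasmic
slit (closed state 79, 89, 91, 175 = LLTV; open state 79, 89, 90, 172,
175 = LLFNV).

The module also owns the two per-residue scales used to score constriction
sites: Kyte–Doolittle hydropathy (dimensionless) and Creighton van der
Waals volumes (Å³).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Kyte & Doolittle hydropathy scale (dimensionless; positive = hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Creighton van der Waals volumes, Å³.
CREIGHTON_VDW_VOLUME = {
    "G": 48.0, "A": 67.0, "S": 73.0, "C": 86.0, "P": 90.0,
    "D": 91.0, "T": 93.0, "N": 96.0, "V": 105.0, "E": 109.0,
    "Q": 114.0, "H": 118.0, "I": 124.0, "L": 124.0, "M": 124.0,
    "K": 135.0, "F": 135.0, "Y": 141.0, "R": 148.0, "W": 163.0,
}

SEGMENT_NAMES = ("TM1", "TM2a", "OMEGA", "TM2b", "TM3", "TM4",
                 "TM5a", "S", "TM5b", "TM6")

DEFAULT_ANNOTATION = "reference_3kcu_synthetic.txt"


class FrameValidationError(ValueError):
    """Raised when a reference annotation violates a frame invariant."""


class ScaleLookupError(KeyError):
    """Raised when a residue has no entry in an amino-acid scale."""


@dataclass(frozen=True)
class SegmentMap:
    """Ordered, non-overlapping secondary-structure segments (1-based, inclusive)."""

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.entries]
        if names != list(SEGMENT_NAMES):
            raise FrameValidationError(
                f"expected segments {SEGMENT_NAMES}, got {tuple(names)}")
        prev_end = None
        for name, start, end in self.entries:
            if start > end:
                raise FrameValidationError(f"segment {name}: start {start} > end {end}")
            if prev_end is not None and start <= prev_end:
                raise FrameValidationError(
                    f"segment {name} starting at {start} overlaps previous "
                    f"segment ending at {prev_end}")
            prev_end = end

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _, _ in self.entries)

    def bounds(self, name: str) -> tuple[int, int]:
        for n, s, e in self.entries:
            if n == name:
                return s, e
        raise KeyError(name)

    def positions(self, name: str) -> range:
        s, e = self.bounds(name)
        return range(s, e + 1)

    def all_positions(self) -> list[int]:
        out: list[int] = []
        for _, s, e in self.entries:
            out.extend(range(s, e + 1))
        return out

    def segment_of(self, position: int) -> str | None:
        for n, s, e in self.entries:
            if s <= position <= e:
                return n
        return None

    @property
    def span(self) -> tuple[int, int]:
        return self.entries[0][1], self.entries[-1][2]


@dataclass(frozen=True)
class ConstrictionDefinition:
    """Reference positions of the two pore constrictions, in sequence order."""

    central: tuple[int, ...] = (75, 202, 209, 212)
    slit_closed: tuple[int, ...] = (79, 89, 91, 175)
    slit_open: tuple[int, ...] = (79, 89, 90, 172, 175)

    def validate_against(self, segments: SegmentMap) -> None:
        for site_name, positions in (("central", self.central),
                                     ("slit_closed", self.slit_closed),
                                     ("slit_open", self.slit_open)):
            if list(positions) != sorted(set(positions)):
                raise FrameValidationError(
                    f"constriction {site_name}: positions must be ascending "
                    f"and duplicate-free, got {positions}")
            for p in positions:
                if segments.segment_of(p) is None:
                    raise FrameValidationError(
                        f"constriction {site_name}: position {p} lies outside "
                        f"every declared segment")


@dataclass(frozen=True)
class AminoAcidScales:
    """Per-residue scales for constriction scoring.

    hydropathy: Kyte–Doolittle values; vdw_volume: Creighton volumes in Å³.
    """

    hydropathy: Mapping[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    vdw_volume: Mapping[str, float] = field(default_factory=lambda: dict(CREIGHTON_VDW_VOLUME))

    def __post_init__(self) -> None:
        for label, table in (("hydropathy", self.hydropathy),
                             ("vdw_volume", self.vdw_volume)):
            if set(table) != set(STANDARD_RESIDUES):
                raise FrameValidationError(
                    f"{label} scale must cover exactly the 20 standard residues")

    def value(self, kind: str, residue: str) -> float:
        if kind == "hydropathy":
            table = self.hydropathy
        elif kind == "volume":
            table = self.vdw_volume
        else:
            raise ValueError(f"unknown scale kind {kind!r}")
        key = residue.upper()
        if key not in table:
            raise ScaleLookupError(
                f"no {kind} value for residue {residue!r} (standard residues only)")
        return table[key]


def scale_value(scales: AminoAcidScales, kind: str, residue: str) -> float:
    """Look up a single residue on the hydropathy or volume scale."""
    return scales.value(kind, residue)


@dataclass(frozen=True)
class ReferenceFrame:
    """The full reference coordinate system used by the pipeline."""

    segments: SegmentMap
    constrictions: ConstrictionDefinition
    reference_sequence: str
    offset: int  # reference number of reference_sequence[0]
    known_residues: Mapping[int, str]
    scales: AminoAcidScales = field(default_factory=AminoAcidScales)

    def __post_init__(self) -> None:
        self.constrictions.validate_against(self.segments)
        lo, hi = self.segments.span
        if not (self.offset <= lo and self.end >= hi):
            raise FrameValidationError(
                f"reference sequence spans {self.offset}-{self.end}; must cover "
                f"segment span {lo}-{hi}")
        for pos, res in sorted(self.known_residues.items()):
            actual = self.residue_at(pos)
            if actual != res:
                raise FrameValidationError(
                    f"reference residue conflict at position {pos}: sequence has "
                    f"{actual!r}, annotation asserts {res!r}")

    @property
    def end(self) -> int:
        return self.offset + len(self.reference_sequence) - 1

    @property
    def positions(self) -> range:
        """All reference positions covered by the reference sequence."""
        return range(self.offset, self.end + 1)

    def residue_at(self, position: int) -> str:
        if not (self.offset <= position <= self.end):
            raise IndexError(
                f"position {position} outside reference span "
                f"{self.offset}-{self.end}")
        return self.reference_sequence[position - self.offset]


def site_positions(frame: ReferenceFrame, site: str, state: str = "n/a") -> list[int]:
    """Reference positions of a constriction site, ascending.

    ``site`` is ``central`` (state must be ``n/a``) or ``slit`` (state
    ``closed`` or ``open``).
    """
    c = frame.constrictions
    if site == "central":
        if state != "n/a":
            raise ValueError("central constriction has no open/closed states")
        return list(c.central)
    if site == "slit":
        if state == "closed":
            return list(c.slit_closed)
        if state == "open":
            return list(c.slit_open)
        raise ValueError(f"slit state must be 'closed' or 'open', got {state!r}")
    raise ValueError(f"site must be 'central' or 'slit', got {site!r}")


def _parse_annotation(text: str) -> dict:
    top: dict[str, str] = {}
    sections: dict[str, list[list[str]]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
            continue
        if current is None:
            if "=" not in line:
                raise FrameValidationError(f"malformed annotation line: {line!r}")
            key, _, value = line.partition("=")
            top[key.strip()] = value.strip()
        else:
            sections[current].append(line.split())
    return {"top": top, "sections": sections}


def load_reference(source: str | None = None) -> ReferenceFrame:
    """Load and validate a reference frame from an annotation file.

    With no argument, loads the bundled default annotation (a synthetic
    FocA-like sequence in 3KCU numbering).  ``source`` may be a path to a
    file in the same format.
    """
    if source is None:
        text = (importlib.resources.files("fntkit.data") / DEFAULT_ANNOTATION
                ).read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    parsed = _parse_annotation(text)
    top, sections = parsed["top"], parsed["sections"]

    try:
        offset = int(top["offset"])
        sequence = top["sequence"].upper()
    except KeyError as exc:
        raise FrameValidationError(f"annotation missing required key: {exc}") from exc

    seg_rows = sections.get("segments", [])
    entries = tuple((name, int(s), int(e)) for name, s, e in seg_rows)
    segments = SegmentMap(entries)

    con_rows = {row[0]: tuple(int(p) for p in row[1:])
                for row in sections.get("constrictions", [])}
    constrictions = ConstrictionDefinition(
        central=con_rows.get("central", ConstrictionDefinition.central),
        slit_closed=con_rows.get("slit_closed", ConstrictionDefinition.slit_closed),
        slit_open=con_rows.get("slit_open", ConstrictionDefinition.slit_open),
    )

    known = {int(pos): res.upper() for pos, res in sections.get("known_residues", [])}

    return ReferenceFrame(segments=segments, constrictions=constrictions,
                          reference_sequence=sequence, offset=offset,
                          known_residues=known)
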