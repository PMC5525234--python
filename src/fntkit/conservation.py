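"""Position-wise conservation statistics over mapped sequence sets.

Conservation is reported per reference position, over the sequences that
actually possess the position (gaps are excluded from the denominator; an
all-gap column is *missing*, not 0%).  Besides individual-residue
frequencies, percentages are reported for residue classes — most
importantly the small/weakly-polar group {G, A, S, T, C} whose group
conservation at helix-helix interfaces is a hallmark of this fold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import MappedSequence
from .reference_frame import GAP, STANDARD_RESIDUES, ReferenceFrame


@dataclass(frozen=True)
class ResidueClassSet:
    name: str
    members: frozenset[str]

    def __post_init__(self):
        bad = self.members - set(STANDARD_RESIDUES)
        if bad:
            raise ValueError(f"class {self.name}: non-standard members {sorted(bad)}")


def default_classes() -> list[ResidueClassSet]:
    """The default class registry.

    small_weakly_polar is the canonical {G,A,S,T,C} group; the other sets
    follow common usage and are configurable (the hydrophobic/hydrophilic
    boundaries in particular are a convention, not a family property).
    """
    make = lambda n, m: ResidueClassSet(n, frozenset(m))
    return [
        make("small_weakly_polar", "GASTC"),
        make("aromatic", "FYW"),
        make("hydrophobic", "AVLIMFCW"),
        make("acidic", "DE"),
        make("basic", "KR"),
        make("hydrophilic", "NQSTHDEKR"),
    ]


@dataclass
class ColumnProfile:
    position: int
    n_effective: int
    counts: dict[str, int]
    frequencies: dict[str, float]
    class_percentages: dict[str, float | None]

    @property
    def missing(self) -> bool:
        return self.n_effective == 0

    def top_residues(self, threshold: float = 0.05) -> list[tuple[str, float]]:
        """Residues at >= threshold frequency, most frequent first."""
        items = sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(r, f) for r, f in items if f >= threshold]


def column_profile(mapped_set: Sequence[MappedSequence], position: int,
                   classes: Sequence[ResidueClassSet] | None = None,
                   ) -> ColumnProfile:
    """Residue counts and class percentages at one reference position."""
    if not mapped_set:
        raise ValueError("column_profile requires a non-empty sequence set")
    classes = default_classes() if classes is None else classes
    counts: Counter[str] = Counter()
    for m in mapped_set:
        res = m.residue_at(position)
        if res != GAP:
            counts[res] += 1
    n = sum(counts.values())
    if n == 0:
        return ColumnProfile(position, 0, {}, {},
                             {c.name: None for c in classes})
    freqs = {r: c / n for r, c in counts.items()}
    class_pct = {
        c.name: 100.0 * sum(f for r, f in freqs.items() if r in c.members)
        for c in classes
    }
    return ColumnProfile(position, n, dict(counts), freqs, class_pct)


def _format_residues(profile: ColumnProfile, report_threshold: float,
                     bracket_threshold: float) -> str:
    parts = []
    for res, freq in profile.top_residues(report_threshold):
        if freq >= bracket_threshold:
            parts.append(f"{res}({freq * 100:.0f})")
        else:
            parts.append(res)
    return ", ".join(parts)


def conservation_table(mapped_set: Sequence[MappedSequence],
                       positions: Iterable[int],
                       frame: ReferenceFrame,
                       classes: Sequence[ResidueClassSet] | None = None,
                       report_threshold: float = 0.05,
                       bracket_threshold: float = 0.30) -> pd.DataFrame:
    """One row per reference position: segment, formatted top residues,
    n_effective and a percentage column per residue class.

    Residues above ``bracket_threshold`` carry their percentage in brackets,
    mirroring the conventional conservation-table layout.  All-gap columns
    propagate as missing values.
    """
    classes = default_classes() if classes is None else classes
    rows = []
    for pos in positions:
        prof = column_profile(mapped_set, pos, classes)
        row: dict[str, object] = {
            "position": pos,
            "segment": frame.segments.segment_of(pos) or "",
            "n_effective": prof.n_effective,
            "residues": (_format_residues(prof, report_threshold,
                                          bracket_threshold)
                         if not prof.missing else ""),
        }
        for c in classes:
            pct = prof.class_percentages[c.name]
            row[c.name] = round(pct, 1) if pct is not None else np.nan
        rows.append(row)
    columns = ["position", "segment", "n_effective", "residues"] + \
        [c.name for c in classes]
    return pd.DataFrame(rows, columns=columns).set_index("position")


#: Region labels, each bounded by (previous segment, next segment); the
#: N/C termini are bounded on one side only.
REGIONS = [
    ("N_term", None, "TM1"),
    ("loop_A", "TM1", "TM2a"),
    ("loop_B", "TM2b", "TM3"),
    ("loop_C", "TM3", "TM4"),
    ("loop_D", "TM4", "TM5a"),
    ("loop_E", "TM5b", "TM6"),
    ("C_term", "TM6", None),
]


def region_lengths(mapped: MappedSequence, frame: ReferenceFrame
                   ) -> dict[str, float]:
    """Lengths of the termini and inter-segment loops of one query.

    A loop length is the count of query residues strictly between the last
    mapped position of one segment and the first mapped position of the
    next; termini count residues outside TM1/TM6.  NaN when a flanking
    segment is entirely unmapped.
    """
    def first_mapped(seg):
        for p in frame.segments.positions(seg):
            if mapped.map.get(p) is not None:
                return mapped.map[p]
        return None

    def last_mapped(seg):
        for p in reversed(frame.segments.positions(seg)):
            if mapped.map.get(p) is not None:
                return mapped.map[p]
        return None

    out: dict[str, float] = {}
    for name, before, after in REGIONS:
        if before is None:
            idx = first_mapped(after)
            out[name] = float(idx) if idx is not None else np.nan
        elif after is None:
            idx = last_mapped(before)
            out[name] = (float(len(mapped.sequence) - idx - 1)
                         if idx is not None else np.nan)
        else:
            lo = last_mapped(before)
            hi = first_mapped(after)
            out[name] = (float(hi - lo - 1)
                         if lo is not None and hi is not None else np.nan)
    return out


def region_length_stats(mapped_set: Sequence[MappedSequence],
                        group_labels: Mapping[str, str],
                        frame: ReferenceFrame) -> pd.DataFrame:
    """Mean and SD of region lengths per group (rows: group; columns:
    MultiIndex (region, mean|sd)).  Groups without members are omitted."""
    per_group: dict[str, list[dict[str, float]]] = {}
    for m in mapped_set:
        label = group_labels.get(m.id)
        if label is None:
            continue
        per_group.setdefault(label, []).append(region_lengths(m, frame))
    records = {}
    for label in sorted(per_group):
        df = pd.DataFrame(per_group[label])
        rec = {}
        for name, _, _ in REGIONS:
            rec[(name, "mean")] = df[name].mean()
            rec[(name, "sd")] = df[name].std(ddof=1) if len(df) > 1 else 0.0
        records[label] = rec
    out = pd.DataFrame.from_dict(records, orient="index")
    if not out.empty:
        out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out
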