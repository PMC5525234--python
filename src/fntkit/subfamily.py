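"""Subfamily-diagnostic position profiles and profile classification.

The eight prokaryotic FNT subfamilies — FocA and FdhC (formate), NirC-α/β/γ
(nitrite), HSC (hydrosulphide) and the uncharacterized YfdC-α/β — were
originally delineated by phylogenetic inference.  This module does NOT
reproduce that phylogeny.  Instead it encodes the subfamily-diagnostic
conservation at fifteen reference positions (each an allowed residue set
with its observed conservation fraction as weight) and classifies a mapped
sequence by weighted profile match.  Sequences whose best and second-best
profile scores are too close are returned as "unclassified" — this margin
rule is this package's stand-in for poorly resolved phylogenetic placement,
not a reproduction of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .mapping import MappedSequence
from .reference_frame import GAP

SUBFAMILIES = ("FocA", "FdhC", "NirC-α", "NirC-β", "NirC-γ", "HSC",
               "YfdC-α", "YfdC-β")

#: Diagnostic positions usable by built-in (table-derived) profiles.
DIAGNOSTIC_POSITIONS = frozenset(
    {202, 212, 79, 90, 172, 86, 92, 93, 100, 208, 34, 37, 113, 167, 254})

# Per position: {subfamily: (residues, conservation %)}; absent entries mean
# no subfamily-specific conservation at that position.
_TABLE: dict[int, dict[str, tuple[str, float]]] = {
    202: {"FocA": ("F", 100), "FdhC": ("F", 99.6), "NirC-α": ("F", 100),
          "NirC-β": ("F", 100), "NirC-γ": ("F", 100), "HSC": ("F", 100),
          "YfdC-α": ("VIM", 99.7), "YfdC-β": ("IMLV", 100)},
    212: {"FocA": ("A", 100), "FdhC": ("A", 93.4), "NirC-α": ("V", 100),
          "NirC-β": ("A", 100), "NirC-γ": ("A", 82.7), "HSC": ("A", 100),
          "YfdC-α": ("V", 71.5), "YfdC-β": ("VIL", 73.5)},
    79: {"FocA": ("LVI", 99), "FdhC": ("LI", 93.4), "NirC-α": ("FY", 98.1),
         "NirC-β": ("L", 100), "NirC-γ": ("L", 99.4), "HSC": ("LVI", 96.0),
         "YfdC-α": ("FY", 100), "YfdC-β": ("F", 73.5)},
    90: {"FocA": ("F", 100), "FdhC": ("VLI", 86.3), "NirC-α": ("VL", 90.9),
         "NirC-β": ("FY", 100), "HSC": ("F", 91.7),
         "YfdC-α": ("FY", 99.7), "YfdC-β": ("F", 100)},
    172: {"FocA": ("N", 100), "FdhC": ("N", 99.6), "NirC-α": ("N", 100),
          "NirC-β": ("N", 100), "NirC-γ": ("N", 99.4), "HSC": ("N", 96.4),
          "YfdC-α": ("G", 99.7), "YfdC-β": ("G", 99.0)},
    86: {"FocA": ("G", 99.3), "FdhC": ("G", 100), "NirC-α": ("G", 91.9),
         "NirC-β": ("G", 100), "NirC-γ": ("NQ", 76), "HSC": ("GS", 95.6),
         "YfdC-α": ("RHD", 81.2), "YfdC-β": ("RHK", 75.5)},
    92: {"FocA": ("S", 100), "FdhC": ("GS", 100), "NirC-α": ("G", 99.0),
         "NirC-β": ("G", 100), "NirC-γ": ("SG", 100), "HSC": ("GSA", 100),
         "YfdC-α": ("E", 100), "YfdC-β": ("E", 90.2)},
    93: {"FocA": ("TS", 100), "FdhC": ("N", 91.3), "NirC-α": ("V", 84.8),
         "NirC-β": ("H", 98.7), "NirC-γ": ("N", 95.5), "HSC": ("N", 88.9),
         "YfdC-α": ("N", 93.1)},
    100: {"FocA": ("KR", 79.9), "FdhC": ("ASG", 99.6), "NirC-α": ("ASG", 99.5),
          "NirC-β": ("GA", 100), "NirC-γ": ("GAS", 100), "HSC": ("GSAT", 97.2),
          "YfdC-α": ("P", 75.1)},
    208: {"FocA": ("E", 100), "FdhC": ("Q", 83), "NirC-α": ("E", 100),
          "NirC-β": ("E", 100), "NirC-γ": ("E", 99.4), "HSC": ("ED", 96.8),
          "YfdC-α": ("AST", 75.6)},
    34: {"FocA": ("TAS", 94.3), "FdhC": ("LMIV", 78.8), "NirC-β": ("F", 100),
         "NirC-γ": ("YF", 98.9), "HSC": ("FY", 98.8), "YfdC-α": ("LI", 93.9),
         "YfdC-β": ("LIVM", 94.1)},
    37: {"FocA": ("LM", 81.2), "FdhC": ("L", 83.0), "NirC-α": ("RK", 95.2),
         "NirC-β": ("GSA", 96.2), "NirC-γ": ("RK", 98.9),
         "YfdC-α": ("SA", 96.4), "YfdC-β": ("TS", 97.1)},
    113: {"FocA": ("N", 77.2), "FdhC": ("N", 90.9), "NirC-α": ("N", 74.3),
          "NirC-β": ("VI", 96.2), "NirC-γ": ("VLIM", 99.4),
          "YfdC-α": ("LVIM", 85.6), "YfdC-β": ("LIV", 99.0)},
    167: {"FocA": ("L", 100), "FdhC": ("S", 75.1), "NirC-α": ("KR", 94.8),
          "NirC-β": ("KR", 100), "NirC-γ": ("RKED", 98.3), "HSC": ("RK", 95.6)},
    254: {"FocA": ("N", 100), "FdhC": ("N", 97.9), "NirC-α": ("N", 100),
          "NirC-β": ("N", 100), "NirC-γ": ("NQ", 72.6), "HSC": ("N", 89.3),
          "YfdC-α": ("FY", 96.1), "YfdC-β": ("FW", 74.5)},
}


@dataclass(frozen=True)
class SubfamilyProfile:
    """Diagnostic residue sets per reference position, with weights in (0,1]."""

    name: str
    diagnostics: Mapping[int, tuple[frozenset[str], float]]
    source: str = "paper_table"

    def __post_init__(self):
        if self.source == "paper_table":
            extra = set(self.diagnostics) - DIAGNOSTIC_POSITIONS
            if extra:
                raise ValueError(
                    f"{self.name}: positions {sorted(extra)} are not "
                    f"diagnostic-table positions")
        for pos, (allowed, weight) in self.diagnostics.items():
            if not (0 < weight <= 1):
                raise ValueError(f"{self.name}@{pos}: weight {weight} not in (0,1]")


def builtin_profiles() -> list[SubfamilyProfile]:
    """The eight built-in profiles, in canonical subfamily order."""
    out = []
    for name in SUBFAMILIES:
        diag = {}
        for pos, row in _TABLE.items():
            if name in row:
                residues, pct = row[name]
                diag[pos] = (frozenset(residues), pct / 100.0)
        out.append(SubfamilyProfile(name=name, diagnostics=diag))
    return out


def score_sequence(mapped: MappedSequence, profile: SubfamilyProfile,
                   gap_penalty: float = 0.5) -> float:
    """Weighted fraction of matched diagnostics, in [-gap_penalty, 1].

    A matched diagnostic contributes its weight; a gap subtracts
    ``gap_penalty`` times the weight (missing evidence weighs less than
    contradicting evidence, which contributes zero); the total is divided
    by the sum of weights.
    """
    total = 0.0
    matched = 0.0
    for pos, (allowed, weight) in profile.diagnostics.items():
        total += weight
        res = mapped.residue_at(pos) if pos in mapped.map else GAP
        if res == GAP:
            matched -= gap_penalty * weight
        elif res in allowed:
            matched += weight
    return matched / total if total else 0.0


def classify(mapped: MappedSequence,
             profiles: Sequence[SubfamilyProfile] | None = None,
             margin_min: float = 0.05,
             gap_penalty: float = 0.5) -> tuple[str, float, float]:
    """(label | 'unclassified', best score, margin to second best).

    Profiles whose normalized scores fall within ``margin_min`` of the best
    form a candidate set.  A unique candidate wins outright.  Otherwise the
    near-tie is resolved toward the candidate whose diagnostics carry the
    strictly largest total weight — the most *specific* profile.  This
    matters because some diagnostic sets nest: a profile with entries at
    only 11 positions (e.g. YfdC-β) can be fully matched by a sequence
    that also matches a 14-position sister profile (YfdC-α), and the
    sequence is then better explained by the profile that constrains more
    positions.  If no candidate is strictly most specific, the sequence is
    'unclassified'.  The reported margin is best minus second-best score.
    """
    profiles = builtin_profiles() if profiles is None else profiles
    if len(profiles) < 2:
        raise ValueError("classification needs at least two profiles")
    scored = [(score_sequence(mapped, p, gap_penalty),
               sum(w for _, w in p.diagnostics.values()), p.name)
              for p in profiles]
    best = max(s for s, _, _ in scored)
    ranked = sorted(scored, key=lambda t: (-t[0], t[2]))
    margin = ranked[0][0] - ranked[1][0]
    candidates = [t for t in scored if best - t[0] < margin_min]
    if len(candidates) == 1:
        return candidates[0][2], candidates[0][0], margin
    top_weight = max(w for _, w, _ in candidates)
    most_specific = [t for t in candidates if t[1] == top_weight]
    if len(most_specific) == 1:
        return most_specific[0][2], most_specific[0][0], margin
    return "unclassified", best, margin


def profiles_to_frame(profiles: Sequence[SubfamilyProfile]) -> pd.DataFrame:
    """Serialize profiles to a tidy table (subfamily, position, residues, weight)."""
    rows = []
    for p in profiles:
        for pos in sorted(p.diagnostics):
            allowed, weight = p.diagnostics[pos]
            rows.append({"subfamily": p.name, "position": pos,
                         "residues": "".join(sorted(allowed)),
                         "weight": weight, "source": p.source})
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> list[SubfamilyProfile]:
    out = []
    for name, sub in df.groupby("subfamily", sort=False):
        diag = {int(r.position): (frozenset(str(r.residues)), float(r.weight))
                for r in sub.itertuples()}
        source = sub["source"].iloc[0] if "source" in sub else "learned"
        out.append(SubfamilyProfile(name=str(name), diagnostics=diag,
                                    source=str(source)))
    return out
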