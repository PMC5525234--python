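"""Constriction-site extraction and CHI/CVV scoring.

Every sequence gets three site records: the central constriction and the
cytoplasmic slit in its closed and open states.  Two cumulative scores
summarize each site:

* CHI, the cumulative hydropathy index — the sum of Kyte–Doolittle
  hydropathy values of the site residues (higher = more hydrophobic);
* CVV, the cumulative van der Waals volume — the sum of Creighton
  per-residue volumes in Å³ (higher = more occluded).

Channels whose sites score far from their group's distribution are flagged
as unusual, by a z-score rule (default) or a percentile rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mapping import MappedSequence, extract_region
from .reference_frame import (GAP, AminoAcidScales, ReferenceFrame,
                              site_positions)


class ScoringError(ValueError):
    """Raised when a residue string cannot be scored."""


#: (site, state) pairs scored for every sequence.
SITE_STATES = (("central", "n/a"), ("slit", "closed"), ("slit", "open"))

#: Typical residue strings per subfamily, shipped for report annotation only
#: (the outlier rules do not use them).  Closed-slit CHI for typical
#: channels spans roughly +7.8 to +11.1, open-slit +7.9 to +13.5.
TYPICAL_SITES = {
    ("central", "n/a"): {
        "FocA": "FFHA", "FdhC": "FFHA", "NirC-α": "FFHV", "NirC-β": "FFHA",
        "NirC-γ": "FFHA", "HSC": "FFHA", "YfdC-α": "YIHV", "YfdC-β": "FLHL",
    },
    ("slit", "closed"): {
        "FocA": "LLTV", "FdhC": "LLTV", "NirC-α": "FLTV", "NirC-β": "LLTV",
        "NirC-γ": "LLTV", "HSC": "LLTV", "YfdC-α": "FLTI", "YfdC-β": "FLTM",
    },
    ("slit", "open"): {
        "FocA": "LLFNV", "FdhC": "LLINV", "NirC-α": "FLLNV", "NirC-β": "LLFNV",
        "NirC-γ": "LLLNV", "HSC": "LLFNV", "YfdC-α": "FLFGI", "YfdC-β": "FLFGM",
    },
}


@dataclass
class ConstrictionScore:
    sequence_id: str
    site: str
    state: str
    residues: str
    chi: float | None
    cvv: float | None
    complete: bool
    flags: list[str] = field(default_factory=list)


def _score(residues: str, table: Mapping[str, float], what: str) -> float:
    if not residues:
        raise ScoringError(f"cannot compute {what} of an empty residue string")
    total = 0.0
    for ch in residues.upper():
        if ch not in table:
            raise ScoringError(
                f"cannot compute {what}: non-standard symbol {ch!r} in "
                f"{residues!r}")
        total += table[ch]
    return total


def chi(residues: str, scales: AminoAcidScales | None = None) -> float:
    """Cumulative hydropathy index: sum of Kyte–Doolittle values."""
    scales = scales or AminoAcidScales()
    return round(_score(residues, scales.hydropathy, "CHI"), 10)


def cvv(residues: str, scales: AminoAcidScales | None = None) -> float:
    """Cumulative vdW volume in Å³: sum of Creighton volumes."""
    scales = scales or AminoAcidScales()
    return _score(residues, scales.vdw_volume, "CVV")


def format_chi(value: float) -> str:
    """Report formatting: positive CHI values carry an explicit '+'."""
    return f"{value:+.1f}"


def score_sites(mapped: MappedSequence, frame: ReferenceFrame,
                scales: AminoAcidScales | None = None
                ) -> list[ConstrictionScore]:
    """Extract and score all three constriction sites of one sequence.

    A site containing a gap is returned with ``complete=False`` and no
    numeric scores; that is data, not an error.
    """
    scales = scales or frame.scales
    out = []
    for site, state in SITE_STATES:
        positions = site_positions(frame, site, state)
        residues = extract_region(mapped, positions)
        complete = GAP not in residues
        out.append(ConstrictionScore(
            sequence_id=mapped.id, site=site, state=state, residues=residues,
            chi=chi(residues, scales) if complete else None,
            cvv=cvv(residues, scales) if complete else None,
            complete=complete))
    return out


def flag_unusual(scores: Sequence[ConstrictionScore],
                 grouping: Mapping[str, str] | None = None,
                 method: str = "zscore",
                 k: float = 2.5,
                 min_group_size: int = 10) -> list[ConstrictionScore]:
    """Flag channels whose CHI/CVV deviate from their group's distribution.

    Scores are partitioned by (group label, site, state); groups with fewer
    than ``min_group_size`` complete members are skipped.  The zscore method
    flags |x - mean| / sd >= k (sd = 0 means no spread, hence no outliers);
    the percentile method flags values outside the [k, 100 - k] percentile
    band and is, by construction, sensitive to duplication of entries.
    Returns flagged copies; the input is not modified.
    """
    if method not in ("zscore", "percentile"):
        raise ValueError(f"unknown outlier method {method!r}")
    grouping = grouping or {}
    out = [replace(s, flags=list(s.flags)) for s in scores]

    buckets: dict[tuple[str, str, str], list[ConstrictionScore]] = {}
    for s in out:
        if not s.complete:
            continue
        key = (grouping.get(s.sequence_id, "all"), s.site, s.state)
        buckets.setdefault(key, []).append(s)

    for key, members in buckets.items():
        if len(members) < min_group_size:
            continue
        for attr, lo_flag, hi_flag in (("chi", "low_chi", "high_chi"),
                                       ("cvv", "low_cvv", "high_cvv")):
            values = np.array([getattr(s, attr) for s in members])
            if method == "zscore":
                mean = values.mean()
                sd = values.std(ddof=0)
                if sd == 0:
                    continue
                for s in members:
                    z = (getattr(s, attr) - mean) / sd
                    if z <= -k:
                        s.flags.append(lo_flag)
                    elif z >= k:
                        s.flags.append(hi_flag)
            else:
                lo = np.percentile(values, k)
                hi = np.percentile(values, 100 - k)
                for s in members:
                    v = getattr(s, attr)
                    if v < lo:
                        s.flags.append(lo_flag)
                    elif v > hi:
                        s.flags.append(hi_flag)
    return out
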