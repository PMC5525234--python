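"""Pairwise identity/similarity over the structured core, and group matrices.

Comparisons are restricted to the reference positions inside the ten
segments (the six TM helices plus the Ω- and S-loops) and, for each pair,
to positions where both sequences are mapped without a gap — so coverage
differences are not penalized twice.  Similarity counts identities plus
substitutions with a positive substitution-matrix score (BLOSUM62 by
default), the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _align
from .mapping import MappedSequence
from .reference_frame import ReferenceFrame


@dataclass
class GroupMatrix:
    labels: list[str]
    identity: pd.DataFrame    # mean percentages, symmetric
    similarity: pd.DataFrame  # mean percentages, symmetric
    n_pairs: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        """Cells as 'identity (similarity)' strings."""
        out = pd.DataFrame(index=self.labels, columns=self.labels, dtype=object)
        for a in self.labels:
            for b in self.labels:
                i = self.identity.loc[a, b]
                s = self.similarity.loc[a, b]
                out.loc[a, b] = ("" if np.isnan(i)
                                 else f"{i:.0f} ({s:.0f})")
        return out


def _core_codes(mapped: MappedSequence, frame: ReferenceFrame,
                positions: Sequence[int]) -> np.ndarray:
    """Encoded residues at the core positions; 255 where gapped."""
    out = np.full(len(positions), 255, dtype=np.uint8)
    full = _align.encode(mapped.sequence)
    for k, p in enumerate(positions):
        idx = mapped.map.get(p)
        if idx is not None:
            out[k] = full[idx]
    return out


def _positive_pairs(matrix: str) -> set[tuple[int, int]]:
    sub = _align.substitution_matrix(matrix)
    pos = set()
    for i in range(20):
        for j in range(20):
            if i != j and sub[i, j] > 0:
                pos.add((i, j))
    return pos


def pairwise_identity_similarity(a: MappedSequence, b: MappedSequence,
                                 frame: ReferenceFrame,
                                 matrix: str = "BLOSUM62",
                                 ) -> tuple[float, float]:
    """(identity %, similarity %) over shared, segment-internal positions.

    Returns (nan, nan) when the two maps share no ungapped core position.
    """
    positions = frame.segments.all_positions()
    ca = _core_codes(a, frame, positions)
    cb = _core_codes(b, frame, positions)
    shared = (ca != 255) & (cb != 255)
    n = int(shared.sum())
    if n == 0:
        return float("nan"), float("nan")
    ia = ca[shared].astype(np.int64)
    ib = cb[shared].astype(np.int64)
    matches = int((ia == ib).sum())
    sub = _align.substitution_matrix(matrix)
    positive = int(((ia != ib) & (sub[ia, ib] > 0)).sum())
    return 100.0 * matches / n, 100.0 * (matches + positive) / n


def group_average_matrix(mapped_set: Sequence[MappedSequence],
                         labels: Mapping[str, str],
                         frame: ReferenceFrame,
                         matrix: str = "BLOSUM62") -> GroupMatrix:
    """Mean pairwise identity/similarity within and between groups.

    Diagonal entries average all unordered within-group pairs; singleton
    groups get a missing diagonal.  Off-diagonal entries average all cross
    pairs.  Group order is sorted label order.
    """
    by_group: dict[str, list[MappedSequence]] = {}
    for m in mapped_set:
        label = labels.get(m.id)
        if label is not None:
            by_group.setdefault(label, []).append(m)
    for members in by_group.values():
        members.sort(key=lambda m: m.id)
    names = sorted(by_group)

    positions = frame.segments.all_positions()
    codes = {g: np.array([_core_codes(m, frame, positions) for m in members])
             for g, members in by_group.items()}
    sub = _align.substitution_matrix(matrix)

    def pair_stats(ca: np.ndarray, cb: np.ndarray) -> tuple[float, float]:
        shared = (ca != 255) & (cb != 255)
        n = int(shared.sum())
        if n == 0:
            return np.nan, np.nan
        ia = ca[shared].astype(np.int64)
        ib = cb[shared].astype(np.int64)
        matches = int((ia == ib).sum())
        positive = int(((ia != ib) & (sub[ia, ib] > 0)).sum())
        return 100.0 * matches / n, 100.0 * (matches + positive) / n

    ident = pd.DataFrame(np.nan, index=names, columns=names)
    simil = pd.DataFrame(np.nan, index=names, columns=names)
    npairs = pd.DataFrame(0, index=names, columns=names, dtype=int)

    for gi, g in enumerate(names):
        cg = codes[g]
        # intra-group
        stats = [pair_stats(cg[i], cg[j])
                 for i, j in combinations(range(len(cg)), 2)]
        npairs.loc[g, g] = len(stats)
        if stats:
            ident.loc[g, g] = float(np.nanmean([s[0] for s in stats]))
            simil.loc[g, g] = float(np.nanmean([s[1] for s in stats]))
        for h in names[gi + 1:]:
            ch = codes[h]
            stats = [pair_stats(ci, cj) for ci in cg for cj in ch]
            npairs.loc[g, h] = npairs.loc[h, g] = len(stats)
            mi = float(np.nanmean([s[0] for s in stats]))
            ms = float(np.nanmean([s[1] for s in stats]))
            ident.loc[g, h] = ident.loc[h, g] = mi
            simil.loc[g, h] = simil.loc[h, g] = ms
    return GroupMatrix(labels=names, identity=ident, similarity=simil,
                       n_pairs=npairs)
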