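"""Mapping query proteins onto the reference frame, plus sequence QC.

Each query is globally aligned to the reference sequence (affine gaps,
BLOSUM62 by default) and the alignment is converted into a monotone map
from reference positions to query indices.  Gap opening inside the declared
reference segments is penalized more heavily (default 3x), which emulates
the structural constraint that transmembrane helices of this family align
without gaps, without requiring homology models.

QC follows the family-screening rules: sequences shorter than 150 residues
are discarded (a six-helix channel cannot be shorter), sequences missing a
segment (low mapping coverage) are discarded, and redundancy is removed by
greedy clustering at 98% identity with the rule that equally identical
sequences from *different* species are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _align
from .reference_frame import GAP, ReferenceFrame


class AlignmentError(ValueError):
    """Raised for unusable alignment input (e.g. an empty sequence)."""


@dataclass(frozen=True)
class AlignParams:
    """Alignment parameters.

    gap_open / gap_extend are positive costs; segment_gap_factor multiplies
    the gap-open cost for gaps opened strictly inside a reference segment.
    score_floor: alignments scoring below it are reported unalignable.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    segment_gap_factor: float = 3.0
    score_floor: float = 0.0


@dataclass
class MappedSequence:
    """A query protein with its monotone map into reference numbering."""

    id: str
    sequence: str
    map: dict[int, int | None]  # reference position -> query index (0-based) or None
    coverage: dict[str, float]  # segment name -> fraction of mapped positions
    score: float
    species: str | None = None

    def residue_at(self, position: int) -> str:
        """Query residue mapped to a reference position, or the gap symbol."""
        idx = self.map[position]
        return GAP if idx is None else self.sequence[idx]


@dataclass
class QcReport:
    kept: list[str] = field(default_factory=list)
    discarded: list[tuple[str, str]] = field(default_factory=list)


def _gap_cost_arrays(frame: ReferenceFrame, params: AlignParams):
    n = len(frame.reference_sequence)
    del_open = np.full(n, params.gap_open, dtype=np.float64)
    ins_open = np.full(n + 1, params.gap_open, dtype=np.float64)
    for pos in frame.positions:
        i = pos - frame.offset
        seg = frame.segments.segment_of(pos)
        if seg is not None:
            # Gap opens are inflated only when the gap starts strictly inside
            # a block of contiguous segment positions (e.g. the TM5a/S/TM5b
            # run): a deletion beginning at a loop|segment boundary is a
            # loop-adjacent event (a whole missing helix opens there for the
            # base cost), while tearing a hole mid-helix stays expensive.
            # Insertions are likewise inflated between two segment positions.
            if pos - 1 >= frame.offset and \
                    frame.segments.segment_of(pos - 1) is not None:
                del_open[i] = params.gap_open * params.segment_gap_factor
            if (pos + 1 <= frame.end
                    and frame.segments.segment_of(pos + 1) is not None):
                ins_open[i + 1] = params.gap_open * params.segment_gap_factor
    return del_open, ins_open


_MATRIX_CACHE: dict[str, np.ndarray] = {}


def _matrix(name: str) -> np.ndarray:
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = _align.substitution_matrix(name)
    return _MATRIX_CACHE[name]


def align_to_reference(record, frame: ReferenceFrame,
                       params: AlignParams = AlignParams(),
                       species: str | None = None) -> MappedSequence:
    """Align one query to the reference and build its position map.

    ``record`` is ``(id, sequence)`` or any object with .id and .seq/.sequence
    (Biopython SeqRecords work).  Raises AlignmentError on empty input; an
    alignment scoring below ``params.score_floor`` is returned with
    ``score`` set but should be filtered by :func:`qc_filter`.
    """
    seq_id, sequence = _as_pair(record)
    return _align_to_frame(seq_id, sequence, frame, params,
                           frame.reference_sequence, species)


def _align_to_frame(seq_id: str, sequence: str, frame: ReferenceFrame,
                    params: AlignParams, target: str,
                    species: str | None = None) -> MappedSequence:
    """Align against ``target`` (a sequence in frame coordinates, same span
    as the reference) and express the map in reference numbering."""
    if not sequence:
        raise AlignmentError(f"{seq_id}: empty sequence")
    a = _align.encode(target)
    b = _align.encode(sequence)
    del_open, ins_open = _gap_cost_arrays(frame, params)
    score, ref_cols, qry_cols = _align.align(
        a, b, _matrix(params.matrix), del_open, ins_open, params.gap_extend)

    posmap: dict[int, int | None] = {}
    for rc, qc in zip(ref_cols.tolist(), qry_cols.tolist()):
        if rc >= 0:
            posmap[frame.offset + rc] = qc if qc >= 0 else None

    coverage = {}
    for name in frame.segments.names:
        positions = frame.segments.positions(name)
        mapped = sum(1 for p in positions if posmap.get(p) is not None)
        coverage[name] = mapped / len(positions)

    return MappedSequence(id=seq_id, sequence=sequence, map=posmap,
                          coverage=coverage, score=float(score),
                          species=species)


def group_consensus(mapped_set: Sequence[MappedSequence],
                    frame: ReferenceFrame) -> str:
    """Majority residue per reference position over a mapped set.

    Positions where the majority of sequences are gapped fall back to the
    reference residue, so the result always spans the full frame and can
    itself serve as an alignment target.
    """
    from collections import Counter

    chars = []
    for pos in frame.positions:
        counts: Counter[str] = Counter()
        for m in mapped_set:
            counts[m.residue_at(pos)] += 1
        res, _ = max(sorted(counts.items()), key=lambda kv: kv[1])
        chars.append(frame.residue_at(pos) if res == GAP else res)
    return "".join(chars)


def refine_maps(mapped_set: Sequence[MappedSequence],
                groups: Mapping[str, str],
                frame: ReferenceFrame,
                params: AlignParams = AlignParams(),
                min_group_size: int = 10) -> list[MappedSequence]:
    """One round of group-wise iterative refinement of position maps.

    Sequences are re-aligned against the majority consensus of their own
    group (in reference coordinates), which emulates the subfamily-specific
    template choice of structure-guided alignment: a query is anchored by
    the residues its own subfamily conserves, not only by those the
    reference happens to share.  This removes rare register slips in
    segments where a subfamily diverges from the reference.  Groups smaller
    than ``min_group_size`` (and ungrouped sequences) keep their original
    maps.
    """
    by_group: dict[str, list[MappedSequence]] = {}
    for m in mapped_set:
        label = groups.get(m.id)
        if label is not None:
            by_group.setdefault(label, []).append(m)
    templates = {label: group_consensus(members, frame)
                 for label, members in by_group.items()
                 if len(members) >= min_group_size}
    out = []
    for m in mapped_set:
        label = groups.get(m.id)
        if label in templates:
            out.append(_align_to_frame(m.id, m.sequence, frame, params,
                                       templates[label], m.species))
        else:
            out.append(m)
    return out


def _as_pair(record) -> tuple[str, str]:
    if isinstance(record, tuple):
        return record[0], str(record[1]).upper()
    seq = getattr(record, "seq", None)
    if seq is None:
        seq = record.sequence
    return record.id, str(seq).upper()


def extract_region(mapped: MappedSequence, positions: Sequence[int]) -> str:
    """Query residues at the given reference positions ('-' where gapped)."""
    out = []
    for p in positions:
        if p not in mapped.map:
            raise IndexError(f"position {p} outside the mapped reference span")
        out.append(mapped.residue_at(p))
    return "".join(out)


def qc_filter(records: Sequence, frame: ReferenceFrame,
              min_length: int = 150,
              min_segment_coverage: float = 0.5,
              params: AlignParams = AlignParams(),
              species: Mapping[str, str] | None = None,
              ) -> tuple[QcReport, dict[str, MappedSequence]]:
    """Length / segment-completeness / alignability screen.

    Returns the QC report plus the maps of all sequences that were long
    enough to align (so callers need not re-align the kept set).
    """
    if not records:
        raise ValueError("qc_filter requires at least one record")
    report = QcReport()
    maps: dict[str, MappedSequence] = {}
    species = species or {}
    for record in records:
        seq_id, sequence = _as_pair(record)
        if len(sequence) < min_length:
            report.discarded.append((seq_id, "too_short"))
            continue
        mapped = align_to_reference((seq_id, sequence), frame, params,
                                    species=species.get(seq_id))
        if mapped.score < params.score_floor:
            report.discarded.append((seq_id, "unalignable"))
            continue
        maps[seq_id] = mapped
        if any(cov < min_segment_coverage for cov in mapped.coverage.values()):
            report.discarded.append((seq_id, "missing_segment"))
            continue
        report.kept.append(seq_id)
    return report, maps


def global_identity(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
                    gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Pairwise identity from a uniform-penalty global alignment.

    Identity = matching columns / length of the shorter sequence, the
    convention of greedy redundancy clustering tools.
    """
    a = _align.encode(seq_a)
    b = _align.encode(seq_b)
    del_open = np.full(a.shape[0], gap_open)
    ins_open = np.full(a.shape[0] + 1, gap_open)
    _, ref_cols, qry_cols = _align.align(a, b, _matrix(matrix),
                                         del_open, ins_open, gap_extend)
    matches = sum(1 for rc, qc in zip(ref_cols.tolist(), qry_cols.tolist())
                  if rc >= 0 and qc >= 0 and a[rc] == b[qc])
    return matches / min(a.shape[0], b.shape[0])


def cluster_redundancy(records: Sequence,
                       species_labels: Mapping[str, str] | None = None,
                       threshold: float = 0.98) -> QcReport:
    """Greedy redundancy removal at an identity threshold.

    Records are visited in descending length (ties by id); each joins the
    first representative at >= threshold identity and is discarded as
    ``redundant`` unless its species label differs from the representative's,
    in which case it is retained.
    """
    species_labels = species_labels or {}
    pairs = [_as_pair(r) for r in records]
    order = sorted(pairs, key=lambda p: (-len(p[1]), p[0]))
    report = QcReport()
    representatives: list[tuple[str, str]] = []
    for seq_id, sequence in order:
        assigned = False
        for rep_id, rep_seq in representatives:
            if global_identity(rep_seq, sequence) >= threshold:
                same_species = (species_labels.get(seq_id) ==
                                species_labels.get(rep_id))
                if same_species:
                    report.discarded.append((seq_id, "redundant"))
                else:
                    report.kept.append(seq_id)
                assigned = True
                break
        if not assigned:
            representatives.append((seq_id, sequence))
            report.kept.append(seq_id)
    # restore input order in the report
    rank = {p[0]: i for i, p in enumerate(pairs)}
    report.kept.sort(key=rank.__getitem__)
    report.discarded.sort(key=lambda t: rank[t[0]])
    return report
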