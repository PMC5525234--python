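"""Synthetic FNT-like cohorts with known ground truth.

The generator emulates the statistical structure of the family as the
conservation and subfamily tables describe it: eight prokaryotic
subfamilies, each with a consensus carrying the subfamily-diagnostic
residues and the near-invariant channel-facing positions; per-position
substitution noise outside those positions; subfamily-dependent loop and
termini lengths; and gene feature tables in which a configurable fraction
of FNT genes sit in operons with their partner enzymes.

Emission model, per sequence:

* protected positions (the diagnostic-table positions plus the annotated
  near-invariant positions) emit the subfamily consensus residue with
  probability ``diagnostic_fidelity``, otherwise a uniformly random other
  residue;
* every other position substitutes with probability ``mutation_rate``
  (uniform over the 19 alternatives, no substitution-matrix bias);
* indels are restricted to the loops and termini — transmembrane segments
  never gain gaps, mirroring the structural constraint real FNTs obey —
  so position maps stay exact at moderate mutation rates.

All randomness flows from one seeded generator; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import REGIONS
from .operon import GeneFeature
from .reference_frame import STANDARD_RESIDUES, ReferenceFrame
from .subfamily import SUBFAMILIES, SubfamilyProfile, builtin_profiles

HYDROPHOBIC_FILL = "AVLIMF"
LOOP_FILL = "GSNPDE"

#: Partner enzyme wired to each subfamily in feature tables (YfdC has none).
PARTNER_BY_SUBFAMILY = {
    "FocA": ("pfl", "pflB", "pyruvate formate lyase"),
    "FdhC": ("fdh", "fdhA", "formate dehydrogenase alpha subunit"),
    "NirC-α": ("nirBD", "nirB", "nitrite reductase large subunit"),
    "NirC-β": ("nirBD", "nirB", "nitrite reductase large subunit"),
    "NirC-γ": ("nirBD", "nirD", "nitrite reductase small subunit"),
    "HSC": ("asrABC", "asrA", "anaerobic sulfite reductase subunit A"),
}

#: (mean, sd) region lengths, residues.  Base values are typical of the
#: formate/nitrite/hydrosulphide subfamilies; overrides encode the reported
#: subfamily peculiarities (long YfdC N-termini, long FocA loop E and
#: FocA/YfdC-α C-termini, short loop A and long loop C in NirC-α).
DEFAULT_REGION_LENGTHS: dict[str, tuple[float, float]] = {
    "N_term": (28, 5), "loop_A": (7, 2), "loop_B": (5, 1), "loop_C": (10, 3),
    "loop_D": (3, 1), "loop_E": (8, 2), "C_term": (12, 4),
}
REGION_LENGTH_OVERRIDES: dict[str, dict[str, tuple[float, float]]] = {
    "YfdC-α": {"N_term": (48, 6), "C_term": (24, 5)},
    "YfdC-β": {"N_term": (48, 6)},
    "NirC-α": {"loop_A": (3, 1), "loop_C": (18, 4)},
    "FocA": {"loop_E": (20, 4), "C_term": (24, 5)},
}


@dataclass
class GeneratorConfig:
    counts: Mapping[str, int] = field(
        default_factory=lambda: {name: 50 for name in SUBFAMILIES})
    mutation_rate: float = 0.1
    diagnostic_fidelity: float = 0.99
    background_divergence: float = 0.2
    loop_length_model: Mapping[str, tuple[float, float]] | None = None
    region_overrides: Mapping[str, Mapping[str, tuple[float, float]]] | None = None
    operon_fraction: float = 0.15
    operon_window: int = 3
    seed: int = 42

    def __post_init__(self):
        for name, p in (("mutation_rate", self.mutation_rate),
                        ("diagnostic_fidelity", self.diagnostic_fidelity),
                        ("background_divergence", self.background_divergence),
                        ("operon_fraction", self.operon_fraction)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("subfamily counts must be >= 0")

    def region_params(self, subfamily: str, region: str) -> tuple[float, float]:
        base = dict(DEFAULT_REGION_LENGTHS)
        if self.loop_length_model:
            base.update(self.loop_length_model)
        overrides = (REGION_LENGTH_OVERRIDES if self.region_overrides is None
                     else self.region_overrides)
        return overrides.get(subfamily, {}).get(region, base[region])


def _protected_positions(frame: ReferenceFrame,
                         profile: SubfamilyProfile) -> set[int]:
    return set(frame.known_residues) | set(profile.diagnostics)


def build_consensus(subfamily: str, frame: ReferenceFrame,
                    profiles: Sequence[SubfamilyProfile] | None = None,
                    background_divergence: float = 0.2) -> str:
    """Consensus sequence over the segment span of the frame (TM1..TM6).

    Diagnostic positions take the first allowed residue of the subfamily
    profile; annotated near-invariant positions take their reference
    residue; remaining segment positions are filled hydrophobically and
    loop positions from the loop alphabet, deterministically (seed 0, so
    the background is shared family-wide).  A ``background_divergence``
    fraction of the filler positions is then re-drawn per subfamily, which
    keeps subfamilies much closer within than between groups.
    """
    profiles = builtin_profiles() if profiles is None else profiles
    try:
        profile = next(p for p in profiles if p.name == subfamily)
    except StopIteration:
        raise KeyError(f"unknown subfamily {subfamily!r}") from None

    lo, hi = frame.segments.span
    rng = np.random.default_rng(0)  # family-wide background
    chars = []
    filler_index: list[int] = []
    for pos in range(lo, hi + 1):
        seg = frame.segments.segment_of(pos)
        if pos in profile.diagnostics:
            chars.append(_first_allowed(profile, pos))
        elif pos in frame.known_residues:
            chars.append(frame.known_residues[pos])
        elif seg is not None:
            chars.append(HYDROPHOBIC_FILL[rng.integers(len(HYDROPHOBIC_FILL))])
            filler_index.append(pos - lo)
        else:
            chars.append(LOOP_FILL[rng.integers(len(LOOP_FILL))])
            filler_index.append(pos - lo)

    if background_divergence > 0 and filler_index:
        sub_rng = np.random.default_rng(1000 + SUBFAMILIES.index(subfamily))
        for i in filler_index:
            if sub_rng.random() < background_divergence:
                pos = lo + i
                pool = (HYDROPHOBIC_FILL
                        if frame.segments.segment_of(pos) else LOOP_FILL)
                choices = _conservative_alternatives(chars[i], pool)
                if choices:
                    chars[i] = choices[sub_rng.integers(len(choices))]
    return "".join(chars)


def _conservative_alternatives(residue: str, pool: str) -> str:
    """Pool residues that are conservative (non-negative BLOSUM62)
    substitutions for ``residue``.

    Between-subfamily divergence at filler positions is restricted to such
    substitutions: real transmembrane cores diverge conservatively, and it
    is precisely this property that keeps the structure-anchored register
    recoverable from sequence alone.
    """
    if residue not in _CONSERVATIVE_CACHE:
        from . import _align

        sub = _align.substitution_matrix("BLOSUM62")
        enc = {aa: k for k, aa in enumerate(STANDARD_RESIDUES)}
        _CONSERVATIVE_CACHE[residue] = "".join(
            b for b in STANDARD_RESIDUES
            if b != residue and sub[enc[residue], enc[b]] >= 0)
    allowed = _CONSERVATIVE_CACHE[residue]
    return "".join(b for b in pool if b in allowed)


_CONSERVATIVE_CACHE: dict[str, str] = {}


def _first_allowed(profile: SubfamilyProfile, pos: int) -> str:
    """First residue of the diagnostic cell, in the table's listing order
    for built-in profiles (alphabetical for learned ones)."""
    from .subfamily import _TABLE

    row = _TABLE.get(pos, {})
    if profile.source == "paper_table" and profile.name in row:
        return row[profile.name][0][0]
    allowed, _ = profile.diagnostics[pos]
    return sorted(allowed)[0]


def _mutate(chars: list[str], mask: np.ndarray, rng: np.random.Generator) -> None:
    for i in np.flatnonzero(mask):
        current = chars[i]
        alternatives = [r for r in STANDARD_RESIDUES if r != current]
        chars[i] = alternatives[rng.integers(19)]


def generate_cohort(config: GeneratorConfig, frame: ReferenceFrame,
                    profiles: Sequence[SubfamilyProfile] | None = None,
                    ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate FASTA records plus ground truth.

    Returns ``(records, ground_truth)`` where records are (id, sequence)
    pairs (ids carry no label information; the label lives only in the
    ground-truth table) and ground truth has one row per sequence with the
    subfamily, species tag and true constriction residue strings.
    """
    profiles = builtin_profiles() if profiles is None else profiles
    rng = np.random.default_rng(config.seed)
    lo, hi = frame.segments.span

    consensus = {}
    protected = {}
    for name in SUBFAMILIES:
        if config.counts.get(name, 0) > 0:
            consensus[name] = build_consensus(
                name, frame, profiles, config.background_divergence)
            prof = next(p for p in profiles if p.name == name)
            mask = np.zeros(hi - lo + 1, dtype=bool)
            for pos in _protected_positions(frame, prof):
                if lo <= pos <= hi:
                    mask[pos - lo] = True
            protected[name] = mask

    assignments = [name for name in SUBFAMILIES
                   for _ in range(config.counts.get(name, 0))]
    if not assignments:
        return [], pd.DataFrame(columns=["id", "subfamily", "species",
                                         "central", "slit_closed",
                                         "slit_open"])
    order = rng.permutation(len(assignments))
    assignments = [assignments[i] for i in order]

    # per-region templates for loop/termini content, per subfamily
    region_bounds = _region_bounds(frame)
    templates: dict[tuple[str, str], str] = {}
    for name in consensus:
        t_rng = np.random.default_rng(2000 + SUBFAMILIES.index(name))
        for region, _, _ in REGIONS:
            bounds = region_bounds[region]
            core = ""
            if bounds is not None:
                a, b = bounds
                core = consensus[name][a - lo:b - lo + 1]
            filler = "".join(LOOP_FILL[t_rng.integers(len(LOOP_FILL))]
                             for _ in range(150))
            templates[(name, region)] = core + filler

    records: list[tuple[str, str]] = []
    truth_rows = []
    seg_entries = frame.segments.entries
    for i, name in enumerate(assignments):
        seq_id = f"FNTSIM{i + 1:05d}"
        cons = consensus[name]
        chars = list(cons)
        n = len(chars)
        u = rng.random(n)
        prot = protected[name]
        flip = (prot & (u < 1.0 - config.diagnostic_fidelity)) | \
               (~prot & (u < config.mutation_rate))
        # loop positions inside the span are replaced below; their flips
        # are harmless but must consume the same draws for determinism
        _mutate(chars, flip, rng)

        # region lengths for this sequence
        lengths = {}
        for region, _, _ in REGIONS:
            mean, sd = config.region_params(name, region)
            lengths[region] = max(0, int(round(rng.normal(mean, sd)))) \
                if sd > 0 else max(0, int(round(mean)))

        # constriction ground truth from the emitted core
        def at(pos: int) -> str:
            return chars[pos - lo]

        central = "".join(at(p) for p in frame.constrictions.central)
        slit_closed = "".join(at(p) for p in frame.constrictions.slit_closed)
        slit_open = "".join(at(p) for p in frame.constrictions.slit_open)

        # assemble: N-term + segments with drawn loops between
        loop_for_next = {after: region for region, _, after in REGIONS
                         if after is not None}
        parts = []
        nterm = list(templates[(name, "N_term")][:lengths["N_term"]])
        _mutate(nterm, rng.random(len(nterm)) < config.mutation_rate, rng)
        parts.append("".join(nterm))
        for k, (seg_name, s, e) in enumerate(seg_entries):
            if k > 0 and seg_name in loop_for_next:
                region = loop_for_next[seg_name]
                loop = list(templates[(name, region)][:lengths[region]])
                _mutate(loop, rng.random(len(loop)) < config.mutation_rate,
                        rng)
                parts.append("".join(loop))
            parts.append("".join(chars[s - lo:e - lo + 1]))
        cterm = list(templates[(name, "C_term")][:lengths["C_term"]])
        _mutate(cterm, rng.random(len(cterm)) < config.mutation_rate, rng)
        parts.append("".join(cterm))

        records.append((seq_id, "".join(parts)))
        truth_rows.append({"id": seq_id, "subfamily": name,
                           "species": f"Synthetica sp. {i + 1:05d}",
                           "central": central, "slit_closed": slit_closed,
                           "slit_open": slit_open})
    return records, pd.DataFrame(truth_rows)


def _region_bounds(frame: ReferenceFrame) -> dict[str, tuple[int, int] | None]:
    """Reference-position bounds of each inter-segment region (None if empty)."""
    out: dict[str, tuple[int, int] | None] = {"N_term": None, "C_term": None}
    for region, before, after in REGIONS:
        if before is None or after is None:
            continue
        _, b_end = frame.segments.bounds(before)
        a_start, _ = frame.segments.bounds(after)
        out[region] = (b_end + 1, a_start - 1) if a_start - b_end > 1 else None
    return out


def generate_feature_table(ground_truth: pd.DataFrame,
                           config: GeneratorConfig
                           ) -> list[GeneFeature]:
    """One contig per sequence: the FNT gene amid filler genes, with a
    partner enzyme inserted for an ``operon_fraction`` of eligible genes.

    Exactly ``round(operon_fraction * n)`` FNT genes receive a partner
    (deterministic placement), chosen among the subfamilies that have known
    partners (YfdC has none).  The partner sits within the scan window on
    the same strand; one filler gene is placed on the opposite strand.
    Adds ``partner_class`` / ``partner_distance`` columns to the ground
    truth, in place.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(ground_truth)
    eligible = [row.id for row in ground_truth.itertuples()
                if row.subfamily in PARTNER_BY_SUBFAMILY]
    k = int(round(config.operon_fraction * n))
    if k > len(eligible):
        raise ValueError(
            f"operon_fraction {config.operon_fraction} needs {k} partnered "
            f"genes but only {len(eligible)} sequences have partnered "
            f"subfamilies")
    chosen = set(rng.choice(eligible, size=k, replace=False)) if k else set()

    gene_len, gap = 900, 100
    n_slots = 2 * config.operon_window + 1
    fnt_slot = config.operon_window
    features: list[GeneFeature] = []
    partner_class = {}
    partner_distance = {}
    for row in ground_truth.itertuples():
        contig = f"ctg_{row.id}"
        strand = "+" if rng.random() < 0.5 else "-"
        partner_slot = None
        if row.id in chosen:
            cls, symbol, product = PARTNER_BY_SUBFAMILY[row.subfamily]
            d = int(rng.integers(1, config.operon_window + 1))
            d = d if rng.random() < 0.5 else -d
            partner_slot = fnt_slot + d
            partner_class[row.id] = cls
            partner_distance[row.id] = d
        else:
            partner_class[row.id] = "none"
            partner_distance[row.id] = 0
        opposite_slot = 0 if fnt_slot != 0 else 1
        if partner_slot == opposite_slot:
            opposite_slot = n_slots - 1
        for slot in range(n_slots):
            start = 1 + slot * (gene_len + gap)
            end = start + gene_len - 1
            if slot == fnt_slot:
                features.append(GeneFeature(
                    contig, start, end, strand, row.id,
                    "formate/nitrite transporter family protein"))
            elif slot == partner_slot:
                cls, symbol, product = PARTNER_BY_SUBFAMILY[row.subfamily]
                features.append(GeneFeature(
                    contig, start, end, strand, f"{symbol}_{row.id}", product))
            else:
                s = ("-" if strand == "+" else "+") \
                    if slot == opposite_slot else strand
                features.append(GeneFeature(
                    contig, start, end, s, f"{row.id}_g{slot}",
                    "hypothetical protein"))
    ground_truth["partner_class"] = ground_truth["id"].map(partner_class)
    ground_truth["partner_distance"] = ground_truth["id"].map(partner_distance)
    return features


def write_fasta(records: Sequence[tuple[str, str]], path: str,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
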