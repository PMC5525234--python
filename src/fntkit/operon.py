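"""Operon-context support for FNT functional assignment.

Prokaryotic FNT genes frequently sit in operons with their partner
metabolic enzymes: formate channels with pyruvate formate lyase (*pfl*) or
formate dehydrogenase (*fdh*), nitrite channels with nitrite reductase
(*nirBD*), hydrosulphide channels with sulfite reductase (*asrABC*).  This
module scans the annotated gene neighborhood (up to three genes up- and
downstream on the same strand, by default) for such partners and converts
a hit into subfamily-level functional support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class GeneFeature:
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    locus_tag: str
    product: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.locus_tag}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: invalid strand {self.strand!r}")


@dataclass
class OperonEvidence:
    fnt_locus: str
    partner_class: str  # pfl | fdh | nirBD | asrABC | none
    partner_locus: str | None
    gene_distance: int  # signed genes away; 0 when no partner
    implied_support: str


#: partner class -> (keywords/gene symbols, implied subfamily support)
DEFAULT_KEYWORDS: dict[str, tuple[tuple[str, ...], str]] = {
    "pfl": (("pyruvate formate lyase", "formate acetyltransferase",
             "pflA", "pflB"), "FocA-formate"),
    "fdh": (("formate dehydrogenase", "fdhA", "fdhB"), "FdhC-formate"),
    "nirBD": (("nitrite reductase", "nirB", "nirD"), "NirC-nitrite"),
    "asrABC": (("sulfite reductase", "asrA", "asrB", "asrC"),
               "HSC-hydrosulphide"),
}


def scan_neighborhood(features: Sequence[GeneFeature], fnt_locus: str,
                      window: int = 3, same_strand: bool = True,
                      ) -> list[tuple[int, GeneFeature]]:
    """Neighbors of an FNT gene as (signed gene distance, feature) pairs.

    Up to ``window`` genes on each side, same contig, restricted to the FNT
    gene's strand when ``same_strand``.  Features are sorted internally by
    (contig, start), so input order never matters.
    """
    ordered = sorted(features, key=lambda f: (f.contig, f.start, f.locus_tag))
    idx = next((i for i, f in enumerate(ordered) if f.locus_tag == fnt_locus),
               None)
    if idx is None:
        raise KeyError(f"locus {fnt_locus!r} not found in the feature table")
    return _neighbors(ordered, idx, window, same_strand)


def _neighbors(ordered: Sequence[GeneFeature], idx: int, window: int,
               same_strand: bool) -> list[tuple[int, GeneFeature]]:
    fnt = ordered[idx]
    out = []
    for i in range(max(0, idx - window), min(len(ordered), idx + window + 1)):
        if i == idx:
            continue
        f = ordered[i]
        if f.contig != fnt.contig:
            continue
        if same_strand and f.strand != fnt.strand:
            continue
        out.append((i - idx, f))
    return out


def assign_operon_support(neighbors: Iterable[tuple[int, GeneFeature]],
                          fnt_locus: str,
                          keyword_registry: Mapping[str, tuple[tuple[str, ...], str]]
                          | None = None) -> OperonEvidence:
    """Partner class of the nearest matching neighbor.

    Matching is case-insensitive substring search of each class keyword in
    the neighbor's product or locus tag.  Equidistant up/downstream hits
    break toward downstream (positive distance).
    """
    registry = DEFAULT_KEYWORDS if keyword_registry is None else keyword_registry
    # nearest first; downstream wins ties
    ranked = sorted(neighbors, key=lambda df: (abs(df[0]), 0 if df[0] > 0 else 1))
    for distance, feature in ranked:
        haystack = f"{feature.product} {feature.locus_tag}".lower()
        for cls, (keywords, support) in registry.items():
            if any(kw.lower() in haystack for kw in keywords):
                return OperonEvidence(fnt_locus=fnt_locus, partner_class=cls,
                                      partner_locus=feature.locus_tag,
                                      gene_distance=distance,
                                      implied_support=support)
    return OperonEvidence(fnt_locus=fnt_locus, partner_class="none",
                          partner_locus=None, gene_distance=0,
                          implied_support="none")


def operon_support_table(features: Sequence[GeneFeature],
                         fnt_loci: Sequence[str],
                         window: int = 3, same_strand: bool = True,
                         keyword_registry=None) -> pd.DataFrame:
    """Evidence for every FNT locus, one row each."""
    ordered = sorted(features, key=lambda f: (f.contig, f.start, f.locus_tag))
    index = {f.locus_tag: i for i, f in enumerate(ordered)}
    rows = []
    for locus in fnt_loci:
        if locus not in index:
            raise KeyError(f"locus {locus!r} not found in the feature table")
        ev = assign_operon_support(
            _neighbors(ordered, index[locus], window, same_strand),
            locus, keyword_registry)
        rows.append({"fnt_locus": ev.fnt_locus,
                     "partner_class": ev.partner_class,
                     "partner_locus": ev.partner_locus or "",
                     "gene_distance": ev.gene_distance,
                     "implied_support": ev.implied_support})
    return pd.DataFrame(rows, columns=["fnt_locus", "partner_class",
                                       "partner_locus", "gene_distance",
                                       "implied_support"])


TSV_COLUMNS = ["contig", "start", "end", "strand", "locus_tag", "product"]


def read_feature_table(path: str) -> list[GeneFeature]:
    """Read gene features from GFF3 (CDS features) or the 6-column TSV dialect."""
    if str(path).endswith((".gff", ".gff3")):
        return _read_gff3(path)
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "locus_tag": str,
                                            "product": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature TSV missing columns: {sorted(missing)}")
    return [GeneFeature(contig=str(r.contig), start=int(r.start),
                        end=int(r.end), strand=str(r.strand),
                        locus_tag=str(r.locus_tag),
                        product="" if pd.isna(r.product) else str(r.product))
            for r in df.itertuples()]


def _read_gff3(path: str) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    out = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        locus = feat.attributes.get("locus_tag", feat.attributes.get("ID", ["?"]))[0]
        product = feat.attributes.get("product", [""])[0]
        out.append(GeneFeature(contig=feat.seqid, start=feat.start,
                               end=feat.end, strand=feat.strand,
                               locus_tag=locus, product=product))
    return out


def write_feature_tsv(features: Sequence[GeneFeature], path: str) -> None:
    df = pd.DataFrame([{"contig": f.contig, "start": f.start, "end": f.end,
                        "strand": f.strand, "locus_tag": f.locus_tag,
                        "product": f.product} for f in features],
                      columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_gff3(features: Sequence[GeneFeature], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.contig, f.start)):
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(f"{f.contig}\tfntkit\tCDS\t{f.start}\t{f.end}\t.\t"
                     f"{f.strand}\t0\t{attrs}\n")
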