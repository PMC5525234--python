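# fntkit

Conservation and constriction-site analysis of **Formate/Nitrite
Transporter (FNT) family** channels.

FNTs export the cytotoxic monovalent anions formate (HCOO⁻), nitrite
(NO₂⁻) and hydrosulphide (HS⁻) from prokaryotic cells. They share an
aquaporin-like hourglass fold of six transmembrane helices (TM2 and TM5
each broken into a/b halves by the Ω- and S-loops) and two narrow pore
regions whose residues determine what the channel passes: the **central
constriction** (positions 75, 202, 209, 212 in the *E. coli* FocA
numbering of PDB 3KCU; canonically Phe-Phe-His-Ala) and the **cytoplasmic
slit**, which the Ω-loop gate switches between a closed state (79, 89,
91, 175 — LLTV) and an open state (79, 89, 90, 172, 175 — LLFNV).
Because FNTs are absent from mammals but common in pathogens, these
constrictions are of direct pharmacological interest.

`fntkit` is for sequence analysts working on this family. It provides:

* a validated reference coordinate frame (segments, constriction
  definitions, known residue identities) in 3KCU numbering;
* structure-anchored mapping of query proteins onto that frame — global
  affine-gap alignment with gap opening penalized 3× inside segment
  blocks, plus group-consensus refinement — and the family's screening
  rules (≥150 residues, segment completeness, 98% redundancy collapse
  with cross-species retention);
* position-wise conservation profiles, including group conservation of
  the small/weakly-polar residues {G,A,S,T,C} at helix interfaces, and
  loop/termini length statistics;
* constriction-site extraction and scoring with the **cumulative
  hydropathy index** CHI = Σ Kyte–Doolittle(residue) and the **cumulative
  vdW volume** CVV = Σ Creighton-volume(residue) [Å³], with z-score or
  percentile flagging of channels with unusual constrictions;
* intra-/inter-subfamily identity and similarity matrices over the
  structured core;
* a diagnostic-residue profile classifier for the eight prokaryotic
  subfamilies (FocA, FdhC, NirC-α/β/γ, HSC, YfdC-α/β);
* operon-context support: scanning ±3 same-strand neighbor genes for
  partner enzymes (*pfl*, *fdh*, *nirBD*, *asrABC*);
* a synthetic-cohort generator with full ground truth, used as the test
  substrate for every stage.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

```python
from fntkit import load_reference, align_to_reference, classify, score_sites, chi, cvv

frame = load_reference()                       # bundled 3KCU-numbered frame
mapped = align_to_reference(("query", frame.reference_sequence), frame)

label, score, margin = classify(mapped)
print(f"subfamily: {label}  (score {score:.2f}, margin {margin:.2f})")
for s in score_sites(mapped, frame):
    print(f"{s.site:7s} {s.state:6s} {s.residues:5s} CHI {s.chi:+.1f}  CVV {s.cvv:.0f}")
```

prints

```
subfamily: FocA  (score 1.00, margin 0.31)
central n/a    FFHA  CHI +4.2  CVV 455
slit    closed LLTV  CHI +11.1  CVV 446
slit    open   LLFNV CHI +11.1  CVV 584
```

Read: the query carries every FocA diagnostic residue (profile score
1.00, comfortably ahead of the next subfamily). Its central constriction
is the canonical FFHA — mildly hydrophobic (CHI +4.2) and 455 Å³ of
side-chain volume — while the cytoplasmic slit is strongly hydrophobic in
both states (CHI +11.1, the top of the typical +7.8…+11.1 closed-state
range). A channel with, say, a YFQS central site would score
`chi("YFQS") = -2.8` — hydrophilic where the family is hydrophobic — and
would be flagged `low_chi` against its subfamily's distribution.

The same stages are available from a shell:

```sh
fntkit simulate --out demo --n-per-subfamily 25 --seed 42
fntkit run-all demo/cohort.fasta --out demo/reports \
       --features demo/features.tsv --species demo/species.tsv
```

which writes TSV reports (QC, position maps, conservation table,
constriction scores with outlier flags, subfamily calls, group
identity/similarity matrix, operon support) plus a run manifest; reruns
are byte-identical.

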