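import pytest

from fntkit.operon import (GeneFeature, assign_operon_support,
                           operon_support_table, read_feature_table,
                           scan_neighborhood, write_feature_tsv, write_gff3)
from fntkit.subfamily import SUBFAMILIES
from fntkit.synthetic import GeneratorConfig, generate_cohort, generate_feature_table


def _contig(genes):
    """Build one contig of 900-bp genes from (locus, strand, product)."""
    out = []
    for k, (locus, strand, product) in enumerate(genes):
        start = 1 + 1000 * k
        out.append(GeneFeature("c1", start, start + 899, strand, locus, product))
    return out


FNT = ("fnt1", "+", "formate/nitrite transporter")
HYP = lambda k, strand="+": (f"hyp{k}", strand, "hypothetical protein")


class TestGeneFeature:
    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            GeneFeature("c", 10, 5, "+", "x")
        with pytest.raises(ValueError):
            GeneFeature("c", 1, 5, "*", "x")


class TestScanNeighborhood:
    def test_partner_within_window_found(self):
        feats = _contig([HYP(1), HYP(2), HYP(3), FNT,
                         ("nirB1", "+", "nitrite reductase large subunit"),
                         HYP(4), HYP(5)])
        neighbors = scan_neighborhood(feats, "fnt1", window=3)
        assert ("nirB1" in {f.locus_tag for _, f in neighbors})
        distances = {f.locus_tag: d for d, f in neighbors}
        assert distances["nirB1"] == 1

    def test_gene_beyond_window_excluded(self):
        feats = _contig([FNT, HYP(1), HYP(2), HYP(3),
                         ("pflB1", "+", "pyruvate formate lyase")])
        neighbors = scan_neighborhood(feats, "fnt1", window=3)
        assert "pflB1" not in {f.locus_tag for _, f in neighbors}

    def test_opposite_strand_excluded(self):
        feats = _contig([FNT, ("pflB1", "-", "pyruvate formate lyase")])
        neighbors = scan_neighborhood(feats, "fnt1", window=3,
                                      same_strand=True)
        assert neighbors == []
        both = scan_neighborhood(feats, "fnt1", window=3, same_strand=False)
        assert {f.locus_tag for _, f in both} == {"pflB1"}

    def test_other_contig_excluded(self):
        feats = _contig([FNT])
        feats.append(GeneFeature("c2", 1, 900, "+", "elsewhere",
                                 "nitrite reductase"))
        assert scan_neighborhood(feats, "fnt1") == []

    def test_unknown_locus_raises(self):
        with pytest.raises(KeyError):
            scan_neighborhood(_contig([FNT]), "nope")

    def test_input_order_invariance(self):
        feats = _contig([HYP(1), FNT, ("nirB1", "+", "nitrite reductase")])
        fwd = scan_neighborhood(feats, "fnt1")
        rev = scan_neighborhood(feats[::-1], "fnt1")
        assert [(d, f.locus_tag) for d, f in fwd] == \
            [(d, f.locus_tag) for d, f in rev]


class TestAssignSupport:
    @pytest.mark.parametrize("product,partner_class,support", [
        ("nitrite reductase large subunit", "nirBD", "NirC-nitrite"),
        ("pyruvate formate lyase", "pfl", "FocA-formate"),
        ("formate acetyltransferase 1", "pfl", "FocA-formate"),
        ("formate dehydrogenase alpha", "fdh", "FdhC-formate"),
        ("anaerobic sulfite reductase subunit A", "asrABC",
         "HSC-hydrosulphide"),
    ])
    def test_keyword_matching(self, product, partner_class, support):
        feats = _contig([FNT, ("g2", "+", product)])
        ev = assign_operon_support(scan_neighborhood(feats, "fnt1"), "fnt1")
        assert ev.partner_class == partner_class
        assert ev.implied_support == support
        assert ev.partner_locus == "g2"

    def test_locus_tag_symbol_matching(self):
        feats = _contig([FNT, ("pflB_0001", "+", "uncharacterized")])
        ev = assign_operon_support(scan_neighborhood(feats, "fnt1"), "fnt1")
        assert ev.partner_class == "pfl"

    def test_no_partner_is_none(self):
        feats = _contig([HYP(1), FNT, HYP(2)])
        ev = assign_operon_support(scan_neighborhood(feats, "fnt1"), "fnt1")
        assert ev.partner_class == "none"
        assert ev.implied_support == "none"
        assert ev.partner_locus is None

    def test_nearest_match_wins_downstream_on_tie(self):
        feats = _contig([("nirB_up", "+", "nitrite reductase"), FNT,
                         ("nirB_dn", "+", "nitrite reductase")])
        ev = assign_operon_support(scan_neighborhood(feats, "fnt1"), "fnt1")
        assert ev.partner_locus == "nirB_dn"
        assert ev.gene_distance == 1


@pytest.fixture(scope="module")
def generated(frame):
    config = GeneratorConfig(counts={s: 5 for s in SUBFAMILIES},
                             operon_fraction=0.2, seed=13)
    _, truth = generate_cohort(config, frame)
    feats = generate_feature_table(truth, config)
    return config, truth, feats


class TestFeatureIo:
    def test_tsv_round_trip(self, generated, tmp_path):
        _, _, feats = generated
        path = tmp_path / "features.tsv"
        write_feature_tsv(feats, path)
        back = read_feature_table(str(path))
        assert [(f.contig, f.start, f.end, f.strand, f.locus_tag, f.product)
                for f in back] == \
            [(f.contig, f.start, f.end, f.strand, f.locus_tag, f.product)
             for f in feats]

    def test_gff3_round_trip(self, generated, tmp_path):
        _, _, feats = generated
        path = tmp_path / "features.gff3"
        write_gff3(feats, path)
        back = read_feature_table(str(path))
        assert {(f.contig, f.start, f.end, f.strand, f.locus_tag, f.product)
                for f in back} == \
            {(f.contig, f.start, f.end, f.strand, f.locus_tag, f.product)
             for f in feats}

    def test_support_matches_ground_truth(self, generated):
        _, truth, feats = generated
        table = operon_support_table(feats, truth.id.tolist())
        merged = table.merge(truth, left_on="fnt_locus", right_on="id")
        assert (merged.partner_class_x == merged.partner_class_y).all()

    def test_extreme_fractions(self, frame):
        for fraction, expected in ((0.0, 0), (0.5, 20)):
            config = GeneratorConfig(counts={s: 5 for s in SUBFAMILIES},
                                     operon_fraction=fraction, seed=13)
            _, truth = generate_cohort(config, frame)
            feats = generate_feature_table(truth, config)
            table = operon_support_table(feats, truth.id.tolist())
            assert int((table.partner_class != "none").sum()) == expected

    def test_full_fraction_on_partnered_subfamilies(self, frame):
        # every subfamily with a known partner enzyme can reach 100% support
        config = GeneratorConfig(counts={"FocA": 5, "HSC": 5},
                                 operon_fraction=1.0, seed=13)
        _, truth = generate_cohort(config, frame)
        feats = generate_feature_table(truth, config)
        table = operon_support_table(feats, truth.id.tolist())
        assert (table.partner_class != "none").all()
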