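import itertools

import pytest

from decodon.trna_identity import (
    IsotypeCall,
    TRNARecord,
    classify_isotype,
    load_ruleset_yaml,
    parse_trna_record,
    read_trnascan_ss,
)


def make_cloverleaf(
    pair1=("G", "C"),
    pair2=("G", "C"),
    pair3=("C", "G"),
    n10="G",
    n20="U",
    anticodon="CAU",
    n37="A",
    n38="A",
    n73="A",
    var_loop="AAUCC",
    gg_anchor=True,
):
    """A canonical cloverleaf with controllable identity positions.

    Layout (0-based): acceptor 5' 0-6, D-stem 9-12, D-loop 13-20 with the
    conserved G18G19 at loop offsets 4-5 and N20 at offset 6, anticodon
    stem 26-30, 7-nt anticodon loop, variable loop, T-arm, acceptor 3',
    discriminator, CCA.
    """
    d_loop = "UACU" + ("GG" if gg_anchor else "AU") + n20 + "U"
    seq = (
        pair1[0] + pair2[0] + pair3[0] + "GCGG"  # acceptor 5'
        + "UA"  # 8, 9a
        + n10 + "CUC"  # D-stem 5'
        + d_loop
        + "GAGC"  # D-stem 3'
        + "A"  # 26
        + "CUGGC"  # anticodon stem 5'
        + "UU" + anticodon + n37 + n38  # anticodon loop (7 nt)
        + "GCCAG"  # anticodon stem 3'
        + var_loop
        + "GGUUC" + "GAAUCCC" + "GAACC"  # T-arm
        + "CCGC" + pair3[1] + pair2[1] + pair1[1]  # acceptor 3'
        + n73
        + "CCA"
    )
    struct = (
        ">>>>>>>" + ".."
        + ">>>>" + "." * len(d_loop) + "<<<<"
        + "."
        + ">>>>>" + "." * 7 + "<<<<<"
        + "." * len(var_loop)
        + ">>>>>" + "." * 7 + "<<<<<"
        + "<<<<<<<"
        + "." * 4
    )
    assert len(seq) == len(struct)
    return seq, struct


class TestParse:
    def test_canonical_positions(self):
        seq, struct = make_cloverleaf()
        rec = parse_trna_record(seq, struct, id="t1")
        assert rec.n1_72 == ("G", "C")
        assert rec.n2_71 == ("G", "C")
        assert rec.n3_70 == ("C", "G")
        assert rec.n10 == "G"
        assert rec.n20 == "U"
        assert rec.d_loop_usual
        assert rec.anticodon == "CAU"
        assert rec.n35 == "A"
        assert rec.n37 == "A"
        assert rec.n38 == "A"
        assert rec.var_loop_len == 5
        # discriminator: the base preceding the 3' CCA
        assert rec.n73 == "A"

    def test_unusual_d_loop_flags_n20_ambiguous(self):
        seq, struct = make_cloverleaf(gg_anchor=False)
        rec = parse_trna_record(seq, struct)
        assert rec.n20 is None
        assert not rec.d_loop_usual

    def test_long_variable_loop_length(self):
        seq, struct = make_cloverleaf(var_loop="AAUCCGGUUCAAGGC")  # 15 nt
        rec = parse_trna_record(seq, struct)
        assert rec.var_loop_len == 15

    def test_rna_dna_equivalence(self):
        seq, struct = make_cloverleaf()
        r1 = parse_trna_record(seq, struct)
        r2 = parse_trna_record(seq.replace("U", "T"), struct)
        assert r1 == r2

    def test_unbalanced_structure_errors(self):
        with pytest.raises(ValueError, match="unbalanced"):
            parse_trna_record("ACGUA", ">>>..")
        with pytest.raises(ValueError, match="fewer than four stems"):
            parse_trna_record("ACGUA", ">>.<<")


class TestBacterialArgMet:
    def test_met_type_record(self):
        """AGG-decoding tRNA with A73 discriminator, no A20, and the
        acceptor-stem pairs supporting methionine identity."""
        seq, struct = make_cloverleaf(
            n73="A", n20="U", pair2=("G", "C"), pair3=("C", "G"),
            anticodon="CCU",
        )
        call = classify_isotype(parse_trna_record(seq, struct), "bacterial_arg_met")
        assert call.isotype == "Met"
        assert call.required_met
        assert "P2:71=G:C" in call.support_met
        assert "P3:70=C:G" in call.support_met

    def test_arg_type_record(self):
        seq, struct = make_cloverleaf(n73="G", n20="A", anticodon="CCU")
        call = classify_isotype(parse_trna_record(seq, struct), "bacterial_arg_met")
        assert call.isotype == "Arg"

    def test_ambiguous_d_loop_unassigned(self):
        seq, struct = make_cloverleaf(n73="A", gg_anchor=False)
        call = classify_isotype(parse_trna_record(seq, struct), "bacterial_arg_met")
        assert call.isotype == "unassigned"
        assert "unusual_d_loop" in call.flags

    def test_mutual_exclusivity_exhaustive(self):
        """No combination of bases at the decision positions satisfies
        both the Arg and the Met required elements (Arg needs A20, Met
        needs not-A20)."""
        for n20, n73 in itertools.product("ACGU", repeat=2):
            rec = TRNARecord(id="x", n20=n20, n73=n73)
            arg = all(
                [(n20 == "A"), (n73 in "AG")]
            )
            met = all([(n73 == "A"), (n20 != "A")])
            assert not (arg and met)
            call = classify_isotype(rec, "bacterial_arg_met")
            if arg:
                assert call.isotype == "Arg"
            elif met:
                assert call.isotype == "Met"
            else:
                assert call.isotype == "unassigned"

    def test_unknown_required_position_is_never_guessed(self):
        rec = TRNARecord(id="x", n20=None, n73="A")
        assert classify_isotype(rec, "bacterial_arg_met").isotype == "unassigned"
        rec = TRNARecord(id="x", n20="U", n73=None)
        assert classify_isotype(rec, "bacterial_arg_met").isotype == "unassigned"


class TestOtherBacterialRulesets:
    def test_trp_requires_g73_without_a20(self):
        rec = TRNARecord(id="x", n20="U", n73="G", n1_72=("A", "U"))
        call = classify_isotype(rec, "bacterial_trp")
        assert call.isotype == "Trp"
        assert "P1:72=A:U" in call.support_met

    def test_gln_weak_pair_and_anticodon_loop(self):
        rec = TRNARecord(
            id="x", n20="U", n73="G", n37="A", n38="G", n10="G",
            n1_72=("U", "A"), n2_71=("G", "C"), n3_70=("G", "C"),
        )
        call = classify_isotype(rec, "bacterial_gln")
        assert call.isotype == "Gln"
        assert set(call.support_met) >= {"P2:71=G:C", "P3:70=G:C", "N38=G", "N10=G"}

    def test_gln_rejected_on_strong_pair(self):
        rec = TRNARecord(id="x", n20="U", n73="G", n37="A", n1_72=("G", "C"))
        assert classify_isotype(rec, "bacterial_gln").isotype == "unassigned"

    def test_gly_acceptor_stem_signature(self):
        rec = TRNARecord(
            id="x", n73="U",
            n1_72=("G", "C"), n2_71=("C", "G"), n3_70=("G", "C"),
        )
        assert classify_isotype(rec, "bacterial_gly").isotype == "Gly"


class TestYeastSerLeu:
    def test_leu_requires_a73_a35_g37(self):
        rec = TRNARecord(id="x", var_loop_len=15, n73="A", n35="A", n37="G")
        assert classify_isotype(rec, "yeast_ser_leu").isotype == "Leu"

    def test_ser_with_typical_g73(self):
        rec = TRNARecord(id="x", var_loop_len=15, n73="G", n35="A", n37="A")
        call = classify_isotype(rec, "yeast_ser_leu")
        assert call.isotype == "Ser"
        assert "N73=G" in call.support_met
        assert call.flags == []

    def test_ser_tolerates_other_discriminators_with_flag(self):
        rec = TRNARecord(id="x", var_loop_len=15, n73="C", n35="A", n37="A")
        call = classify_isotype(rec, "yeast_ser_leu")
        assert call.isotype == "Ser"
        assert "non_G73_serine" in call.flags

    def test_short_variable_loop_unassigned(self):
        rec = TRNARecord(id="x", var_loop_len=10, n73="A", n35="A", n37="G")
        assert classify_isotype(rec, "yeast_ser_leu").isotype == "unassigned"


class TestIO:
    def test_unknown_ruleset_errors(self):
        with pytest.raises(ValueError, match="unknown ruleset"):
            classify_isotype(TRNARecord(id="x"), "nope")

    def test_read_trnascan_ss_blocks(self, tmp_path):
        seq, struct = make_cloverleaf()
        text = (
            "chr1.trna1 (100-176)\tLength: 76 bp\n"
            "Type: Met\tAnticodon: CAT at 34-36\n"
            f"Seq: {seq}\n"
            f"Str: {struct}\n"
            "\n"
            "chr1.trna2 (200-276)\tLength: 76 bp\n"
            "Type: Arg\tAnticodon: CCT at 34-36\n"
            f"Seq: {seq}\n"
            f"Str: {struct}\n"
        )
        p = tmp_path / "trnas.ss"
        p.write_text(text)
        blocks = read_trnascan_ss(p)
        assert [b[0] for b in blocks] == ["chr1.trna1", "chr1.trna2"]
        assert blocks[0][1] == seq

    def test_yaml_ruleset_merge(self, tmp_path):
        p = tmp_path / "rules.yaml"
        p.write_text(
            "custom_pro:\n"
            "  uses_n20: false\n"
            "  isotypes:\n"
            "    - isotype: Pro\n"
            "      required: ['N73=A']\n"
            "      support: []\n"
        )
        load_ruleset_yaml(p)
        rec = TRNARecord(id="x", n73="A")
        assert classify_isotype(rec, "custom_pro").isotype == "Pro"
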