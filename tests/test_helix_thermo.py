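"""Nearest-neighbor helix scoring, information content, FASTA parsing."""

import textwrap

import pytest

from ribopinch import HelixDuplex, helix_dG37, info_bits, parse_construct_fasta
from ribopinch.errors import ParameterTableError, ValidationError
from ribopinch.helix_thermo import NNParamTable

# Published Watson-Crick nearest-neighbor dG37 values (Xia et al. 1998),
# kcal/mol -- an independent literature anchor for the bundled table.
XIA_WC = {
    "AA/UU": -0.93, "AU/AU": -1.10, "UA/UA": -1.33, "CU/AG": -2.08,
    "CA/UG": -2.11, "GU/AC": -2.24, "GA/UC": -2.35, "CG/CG": -2.36,
    "GG/CC": -3.26, "GC/GC": -3.42,
}


class TestDuplexValidation:
    def test_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            HelixDuplex("GAC", "GAC")  # middle A-A position

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            HelixDuplex("GGC", "GC")

    def test_gu_wobble_accepted(self):
        d = HelixDuplex("GGU", "GCC")  # G-C, G-C, U-G from the 3' side
        assert d.n_bp == 3

    def test_t_normalized_to_u(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ribopinch.helix_thermo"):
            d = HelixDuplex("GCTA", "TAGC")
        assert d.strand5 == "GCUA"
        assert "T->U" in caplog.text

    def test_non_rna_alphabet_rejected(self):
        with pytest.raises(ValidationError):
            HelixDuplex("GXC", "GCC")


class TestHelixEnergy:
    def test_single_pair_is_initiation_only(self, nn_params):
        """A 1-bp G-C duplex has no stacks: dG = initiation."""
        assert helix_dG37(HelixDuplex("G", "C"), nn_params) == pytest.approx(
            nn_params.init_dG37
        )
        # A-U single pair additionally pays two terminal penalties
        assert helix_dG37(HelixDuplex("A", "U"), nn_params) == pytest.approx(
            nn_params.init_dG37 + 2 * nn_params.terminal_AU_penalty
        )

    def test_four_bp_hand_summed(self, nn_params):
        """GCGC/GCGC: initiation + GC/GC + CG/CG + GC/GC, summed by hand
        from the bundled table."""
        expected = (
            nn_params.init_dG37
            + 2 * nn_params.stack_dG37["GC/GC"]
            + nn_params.stack_dG37["CG/CG"]
        )
        got = helix_dG37(HelixDuplex("GCGC", "GCGC"), nn_params)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_gc_extension_strictly_stabilizes(self, nn_params):
        """Appending a G-C pair always lowers dG37: every step adjacent
        to a C-G or G-C pair is stabilizing in the bundled table."""
        gc_adjacent = [
            k for k in nn_params.stack_dG37
            if k[1] == "G" and k[3] == "C" or k[1] == "C" and k[3] == "G"
        ]
        assert gc_adjacent and all(
            nn_params.stack_dG37[k] < 0 for k in gc_adjacent
        )
        base = HelixDuplex("AGCU", "AGCU")
        extended = HelixDuplex("AGCUG", "CAGCU")  # one more G-C at the end
        assert helix_dG37(extended, nn_params) < helix_dG37(base, nn_params)

    def test_strand_flip_symmetry(self, nn_params):
        for s5, s3 in [("GGAC", "GUCC"), ("AUGC", "GCAU"), ("GGUGG", "CCGCC")]:
            d = HelixDuplex(s5, s3)
            assert helix_dG37(d, nn_params) == pytest.approx(
                helix_dG37(d.flipped(), nn_params), abs=1e-12
            )

    def test_stepwise_additivity(self, nn_params):
        """Growing all-G/C helices differ by exactly one stack term
        (no terminal-penalty bookkeeping changes)."""
        s5, s3 = "GCGGC", "GCCGC"
        for n in range(2, 5):
            shorter = HelixDuplex(s5[:n], s3[-n:])
            longer = HelixDuplex(s5[: n + 1], s3[-(n + 1):])
            step = nn_params.stack(shorter.pairs[-1], longer.pairs[-1])
            assert helix_dG37(longer, nn_params) == pytest.approx(
                helix_dG37(shorter, nn_params) + step, abs=1e-12
            )

    def test_hairpin_loop_penalty(self, nn_params):
        d = HelixDuplex("GGAC", "GUCC", closing_loop=4)
        open_dG = helix_dG37(d, nn_params)
        capped = helix_dG37(d, nn_params, include_loop=True)
        assert capped == pytest.approx(
            open_dG + nn_params.hairpin_loop_dG37[4], abs=1e-12
        )

    def test_loop_requires_length(self, nn_params):
        with pytest.raises(ValidationError):
            helix_dG37(HelixDuplex("GGC", "GCC"), nn_params, include_loop=True)


class TestParamTable:
    def test_bundled_matches_published_wc_values(self, nn_params):
        """Bundled stacks agree with the Xia et al. 1998 literature
        values within table rounding (0.05 kcal/mol)."""
        for key, lit in XIA_WC.items():
            assert nn_params.stack_dG37[key] == pytest.approx(lit, abs=0.05), key

    def test_all_wc_gu_steps_present(self, nn_params):
        assert len(nn_params.stack_dG37) == 36

    def test_incomplete_table_rejected(self, nn_params):
        stacks = dict(nn_params.stack_dG37)
        stacks.pop("AA/UU")
        with pytest.raises(ParameterTableError):
            NNParamTable(stacks, 4.1, 0.5)

    def test_asymmetric_table_rejected(self, nn_params):
        stacks = dict(nn_params.stack_dG37)
        stacks["AA/UU"] = stacks["UU/AA"] + 1.0
        with pytest.raises(ParameterTableError):
            NNParamTable(stacks, 4.1, 0.5)


class TestViennaCrossCheck:
    def test_stack_increments_match_vienna(self, nn_params):
        """Independent route: base-pair-extension energy differences
        computed by ViennaRNA's Turner-2004 evaluator match the bundled
        table's stack + terminal-penalty bookkeeping."""
        RNA = pytest.importorskip("RNA")

        def vienna_hp(stem_top, stem_bot):
            seq = stem_top + "GAAA" + stem_bot
            n = len(stem_top)
            return RNA.fold_compound(seq).eval_structure(
                "(" * n + "...." + ")" * n
            )

        cases = [("A", "U", "A", "U"), ("G", "C", "U", "G"), ("U", "G", "G", "C")]
        for X, z, Y, w in cases:
            # vienna: add pair (X,z) below a stem starting with (Y,w)
            dE = vienna_hp(X + Y + "CGCG", "CGCG" + w + z) - vienna_hp(
                Y + "CGCG", "CGCG" + w
            )
            pen = nn_params.terminal_AU_penalty
            au_gu = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
            expected = (
                nn_params.stack((X, z), (Y, w))
                + (pen if (X, z) in au_gu else 0.0)
                - (pen if (Y, w) in au_gu else 0.0)
            )
            assert dE == pytest.approx(expected, abs=0.011)


class TestInfoBits:
    @pytest.mark.parametrize("bp,bits", [(0, 0), (5, 10), (7, 14)])
    def test_two_bits_per_pair(self, bp, bits):
        assert info_bits(bp) == bits

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            info_bits(-1)


class TestFastaParsing:
    def test_paired_records(self, tmp_path):
        fa = tmp_path / "helices.fa"
        fa.write_text(">h1/5\nGGACGC\n>h1/3\nGCGUCC\n")
        (d,) = parse_construct_fasta(fa)
        assert d.construct_id == "h1"
        assert d.n_bp == 6

    def test_ampersand_dialect(self, tmp_path):
        fa = tmp_path / "helices.fa"
        fa.write_text(">h2\nGGAC&GUCC\n")
        (d,) = parse_construct_fasta(fa)
        assert d.construct_id == "h2" and d.n_bp == 4

    def test_t_normalization_in_fasta(self, tmp_path):
        fa = tmp_path / "dna.fa"
        fa.write_text(">d/5\nGGTC\n>d/3\nGACC\n")
        (d,) = parse_construct_fasta(fa)
        assert "U" in d.strand5 and "T" not in d.strand5

    def test_mismatched_position_rejected(self, tmp_path):
        fa = tmp_path / "bad.fa"
        fa.write_text(">b\nGAC&GAC\n")
        with pytest.raises(ValidationError):
            parse_construct_fasta(fa)

    def test_unpaired_record_rejected(self, tmp_path):
        fa = tmp_path / "orphan.fa"
        fa.write_text(">only/5\nGGAC\n")
        with pytest.raises(ValidationError):
            parse_construct_fasta(fa)
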