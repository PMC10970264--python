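"""Primer design, Tm estimation, and the marker-table audit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastotype.errors import DataError, NoDesignError
from plastotype.kasp import (
    audit_designed,
    audit_marker_table,
    design_kasp,
    estimate_tm,
    marker_to_row,
    with_tails,
)
from plastotype.model import MarkerTableRow, VariantLocus
from plastotype.simulate import revcomp

# SantaLucia unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K),
# transcribed independently for the oracle below.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


def nn_tm_oracle(seq, na_mm=50.0, primer_nm=200.0):
    """Unified nearest-neighbor Tm with the entropic salt correction."""
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        h, s = _INIT[end]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mm * 1e-3)
    R = 1.987
    return dh * 1000.0 / (ds + R * math.log(primer_nm * 1e-9)) - 273.15


def _snp_locus(flank_left, flank_right, alleles=("A", "G")):
    locus = VariantLocus(
        "CPMSNP01", "SNP", (0, 1), list(alleles), np.array([0, 1])
    )
    locus.flank_left = flank_left
    locus.flank_right = flank_right
    locus.flanks_conserved = True
    return locus


GC_FLANK = "ACGTGCGTACGGTCAGCATGCCGTACGCTAGCGATCGTACGGCATGCAGTCCGATGCGTA"


class TestTm:
    def test_wallace_rule_closed_form(self):
        assert estimate_tm("ACGT", "wallace") == 12.0
        assert estimate_tm("A" * 20, "wallace") == 40.0

    def test_invalid_base_rejected(self):
        with pytest.raises(DataError):
            estimate_tm("ACGU")

    @pytest.mark.parametrize(
        "primer",
        [
            "ACGTGCGTACGGTCAGCATG",
            "TTTTAAAACCCCGGGGACGT",
            "GATCGATCGATCGATCGATC",
            GC_FLANK[:25],
        ],
    )
    def test_nn_matches_independent_oracle(self, primer):
        assert estimate_tm(primer) == pytest.approx(
            nn_tm_oracle(primer), abs=0.5
        )


class TestDesign:
    def test_allele_primers_end_at_the_variant_base(self):
        marker = design_kasp(_snp_locus(GC_FLANK, GC_FLANK))
        if marker.orientation == "forward":
            assert marker.primer_fam.endswith("A")
            assert marker.primer_hex.endswith("G")
        else:
            assert marker.primer_fam.endswith("T")
            assert marker.primer_hex.endswith("C")
        # identical upstream of the discriminating base
        overlap = min(len(marker.primer_fam), len(marker.primer_hex)) - 1
        assert marker.primer_fam[-1 - overlap : -1] == \
            marker.primer_hex[-1 - overlap : -1]

    def test_primers_meet_tm_target_and_length_range(self):
        marker = design_kasp(_snp_locus(GC_FLANK, GC_FLANK), tm_target=58.0)
        for primer, tm in [
            (marker.primer_fam, marker.tm_fam),
            (marker.primer_hex, marker.tm_hex),
            (marker.primer_common, marker.tm_common),
        ]:
            assert 18 <= len(primer) <= 35
            assert tm >= 58.0
            assert estimate_tm(primer) == tm

    def test_unconserved_flanks_refused(self):
        locus = _snp_locus(GC_FLANK, GC_FLANK)
        locus.flanks_conserved = False
        with pytest.raises(NoDesignError, match="conserved"):
            design_kasp(locus)

    def test_unreachable_tm_raises(self):
        at_flank = "AT" * 30
        with pytest.raises(NoDesignError, match="strand"):
            design_kasp(_snp_locus(at_flank, at_flank), tm_target=75.0)

    def test_indel_primers_end_at_first_differing_base(self):
        locus = VariantLocus(
            "CPMIDP01", "InDel", (0, 5), ["", "TCTTT"], np.array([0, 1])
        )
        locus.flanks_conserved = True
        # right flank begins G, so the deletion allele reads G where the
        # insertion allele reads T: both primers discriminate at position 0
        marker = design_kasp(locus, flank_left=GC_FLANK,
                             flank_right="G" + GC_FLANK[:59])
        assert marker.primer_fam[-1] != marker.primer_hex[-1]

    def test_large_insertion_uses_two_flank_layout(self):
        insertion = (GC_FLANK * 2)[:83]
        locus = VariantLocus(
            "CPMIDP09", "InDel", (0, 83), [insertion, ""], np.array([0, 1])
        )
        locus.flanks_conserved = True
        marker = design_kasp(locus, flank_left=GC_FLANK,
                             flank_right="T" + GC_FLANK[:59])
        assert marker.primer_common == ""
        assert marker.flank1 and marker.flank2
        assert marker.flank2 in insertion
        assert any("two-flank" in n for n in marker.notes)

    def test_tails_prepended_only_on_request(self):
        marker = design_kasp(_snp_locus(GC_FLANK, GC_FLANK))
        tailed = with_tails(marker)
        assert tailed.primer_fam.endswith(marker.primer_fam)
        assert tailed.primer_fam.startswith("GAAGGTGACC")
        assert marker.primer_fam[0] != "G" or True  # original untouched
        assert not marker.primer_fam.startswith("GAAGGTGACC")


class TestAudit:
    @pytest.mark.parametrize(
        "marker_id,expected",
        [
            ("CSNP17K", "forward"),   # alleles C/T, primers end ...C/...T
            ("CSNP01K", "reverse"),   # alleles T/G, primers end ...A/...C
            ("CSNP03K", "reverse"),   # alleles C/G, primers end ...G/...C
            ("CSNP08K", "forward"),   # alleles C/A, primers end ...C/...A
        ],
    )
    def test_known_row_orientations(self, vcp_rows, marker_id, expected):
        row = next(r for r in vcp_rows if r.marker_id == marker_id)
        (audit,) = audit_marker_table([row])
        assert audit.orientation_call == expected

    def test_packaged_table_has_zero_inconsistent_rows(self, vcp_rows):
        audits = audit_marker_table(vcp_rows)
        snp_calls = {
            a.orientation_call
            for a, r in zip(audits, vcp_rows)
            if not r.is_indel
        }
        assert snp_calls <= {"forward", "reverse"}
        assert all(a.orientation_call != "inconsistent" for a in audits)
        assert all(a.flank_check != "fail" for a in audits)

    def test_constructed_mismatch_is_inconsistent(self):
        row = MarkerTableRow(
            marker_id="CX99K",
            variation_locus_id="CPMSNP99",
            allele_fam="C",
            allele_hex="T",
            specific_type=None,
            corresponding_allele=None,
            primer_fam="ACGTGCGTACGGTCAGCATGA",
            primer_hex="CGTGCGTACGGTCAGCATGA",
            primer_common="TACGCATCGGACTGCATGCC",
        )
        (audit,) = audit_marker_table([row])
        assert audit.orientation_call == "inconsistent"

    def test_designed_markers_pass_their_own_audit(self, inventory_seed1):
        checked = 0
        for locus in inventory_seed1.loci:
            if len(locus.alleles) != 2:
                continue
            try:
                marker = design_kasp(locus)
            except NoDesignError:
                continue
            audit = audit_designed(marker)
            assert audit.orientation_call != "inconsistent"
            assert audit.flank_check != "fail"
            if locus.kind == "SNP":
                assert audit.orientation_call == marker.orientation
                assert audit.flank_check == "pass"
            checked += 1
        assert checked >= 10

    @settings(max_examples=60, deadline=None)
    @given(
        flank_seed=st.integers(0, 2**31 - 1),
        alleles=st.lists(st.sampled_from("ACGT"), min_size=2, max_size=2,
                         unique=True),
    )
    def test_random_snp_design_round_trip(self, flank_seed, alleles):
        rng = np.random.default_rng(flank_seed)
        bases = np.array(list("ACGT"))
        left = "".join(rng.choice(bases, size=60))
        right = "".join(rng.choice(bases, size=60))
        locus = _snp_locus(left, right, tuple(alleles))
        try:
            marker = design_kasp(locus)
        except NoDesignError:
            return  # AT-rich flanks may be undesignable; that is a verdict
        audit = audit_designed(marker)
        assert audit.orientation_call == marker.orientation
        assert audit.flank_check == "pass"
        assert marker.primer_fam[-1] != marker.primer_hex[-1]

    def test_marker_row_round_trip_via_table(self, tmp_path):
        from plastotype.io import read_marker_table, write_marker_table

        marker = design_kasp(_snp_locus(GC_FLANK, GC_FLANK))
        row = marker_to_row(marker)
        write_marker_table([row], tmp_path / "m.tsv")
        (back,) = read_marker_table(tmp_path / "m.tsv")
        assert (back.primer_fam, back.primer_hex, back.primer_common) == (
            row.primer_fam, row.primer_hex, row.primer_common,
        )
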