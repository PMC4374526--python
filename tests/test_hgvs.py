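"""HGVS c.-notation parsing, application and naming."""

import numpy as np
import pytest

from genoscreen.effects import CdsModel
from genoscreen.hgvs import (
    HgvsParseError,
    HgvsVariant,
    MultipleEditsError,
    ReferenceMismatchError,
    apply_variant,
    c_span_length,
    codons_spanned,
    format_hgvs,
    name_variant,
    parse_hgvs_c,
    revcomp,
)


class TestParse:
    def test_seven_bp_deletion(self):
        v = parse_hgvs_c("c.7137_7143del")
        assert v.kind == "deletion"
        assert v.span_length == 7

    def test_substitution_with_spaces(self):
        v = parse_hgvs_c("c.1015A > T")
        assert v.kind == "substitution"
        assert (v.start, v.ref_base, v.insert) == (1015, "A", "T")

    def test_inversion_span(self):
        v = parse_hgvs_c("c.6393_6413inv")
        assert v.kind == "inversion"
        assert v.span_length == 21

    def test_delins_external_token(self):
        v = parse_hgvs_c("c.-1954_6926delinsCM000150.2:1390060_1390808")
        assert v.kind == "delins"
        assert v.start == -1954 and v.end == 6926
        # span crosses the missing zero: 1954 upstream + 6926 CDS bases
        assert v.span_length == 8880
        assert v.external_insert == "CM000150.2:1390060_1390808"
        assert v.insert_len == 1390808 - 1390060 + 1

    def test_single_position_deletion(self):
        v = parse_hgvs_c("c.3508del")
        assert v.kind == "deletion" and v.span_length == 1

    def test_insertion(self):
        v = parse_hgvs_c("c.4_5insACGT")
        assert v.kind == "insertion" and v.insert == "ACGT"

    def test_roundtrip_format(self):
        for text in ["c.7137_7143del", "c.1015A>T", "c.6393_6413inv", "c.3508del",
                     "c.4_5insACGT", "c.10_12delinsAA", "c.5_6dup"]:
            assert format_hgvs(parse_hgvs_c(text)) == text

    @pytest.mark.parametrize("bad", [
        "g.100A>T", "c.0A>T", "c.10_5del", "c.xyz", "c.5_5insA", "c.10-12del",
        "c.5A>", "c.delins",
    ])
    def test_malformed(self, bad):
        with pytest.raises(HgvsParseError):
            parse_hgvs_c(bad)

    def test_zero_coordinate_rejected_in_constructor(self):
        with pytest.raises(HgvsParseError):
            HgvsVariant("deletion", 0, 5)


class TestSpanLength:
    def test_same_sign(self):
        assert c_span_length(7137, 7143) == 7
        assert c_span_length(5, 5) == 1

    def test_crossing_zero(self):
        # -2, -1, 1, 2 = 4 bases, not 5
        assert c_span_length(-2, 2) == 4
        assert c_span_length(-1954, 6926) == 8880


class TestApply:
    def test_inversion(self, tiny_cds):
        out = apply_variant(tiny_cds, parse_hgvs_c("c.4_9inv"))
        assert out[tiny_cds.upstream_len:] == "ATGGGGTTTGGGTAA"

    def test_substitution(self, tiny_cds):
        out = apply_variant(tiny_cds, parse_hgvs_c("c.4A>T"))
        assert out[tiny_cds.upstream_len:] == "ATGTAACCCGGGTAA"

    def test_deletion(self, tiny_cds):
        out = apply_variant(tiny_cds, parse_hgvs_c("c.4_5del"))
        assert out[tiny_cds.upstream_len:] == "ATGACCCGGGTAA"

    def test_upstream_coordinates(self, tiny_cds):
        # c.-1 is the last upstream base
        out = apply_variant(tiny_cds, parse_hgvs_c("c.-1T>G"))
        assert out == tiny_cds.upstream_seq[:-1] + "G" + tiny_cds.cds_seq

    def test_reference_mismatch(self, tiny_cds):
        with pytest.raises(ReferenceMismatchError):
            apply_variant(tiny_cds, parse_hgvs_c("c.4C>T"))

    def test_out_of_span(self, tiny_cds):
        with pytest.raises(ValueError):
            apply_variant(tiny_cds, parse_hgvs_c("c.999A>T"))

    def test_inversion_involution(self, tiny_cds):
        v = parse_hgvs_c("c.4_9inv")
        once = apply_variant(tiny_cds, v)
        twice = apply_variant(
            CdsModel(once[tiny_cds.upstream_len:], tiny_cds.upstream_seq), v
        )
        assert twice[tiny_cds.upstream_len:] == tiny_cds.cds_seq


class TestCodonsSpanned:
    def test_eight_codon_inversion(self):
        first, last, count, clipped = codons_spanned(parse_hgvs_c("c.6393_6413inv"))
        assert (first, last, count, clipped) == (2131, 2138, 8, False)

    def test_first_codon(self):
        assert codons_spanned(parse_hgvs_c("c.1_3del"))[2] == 1

    def test_straddling_codon_boundary(self):
        assert codons_spanned(parse_hgvs_c("c.3_4del"))[2] == 2

    def test_upstream_clipped(self):
        first, last, count, clipped = codons_spanned(parse_hgvs_c("c.-5_6del"))
        assert (first, last, count, clipped) == (1, 2, 2, True)

    def test_entirely_upstream_rejected(self):
        with pytest.raises(ValueError):
            codons_spanned(parse_hgvs_c("c.-10_-5del"))


def brute_force_deletions(ref: str, mut: str) -> list[tuple[int, int]]:
    """All (start, end) 1-based deletions of ref yielding mut."""
    k = len(ref) - len(mut)
    assert k > 0
    return [
        (i + 1, i + k)
        for i in range(len(ref) - k + 1)
        if ref[:i] + ref[i + k:] == mut
    ]


class TestNameVariant:
    def test_three_prime_shifted_deletion(self):
        ref = CdsModel("ATGAAACCCTAA")
        mut = "ATGACCCTAA"
        v = name_variant(ref, mut)
        assert format_hgvs(v) == "c.5_6del"
        # oracle: 3'-most among all equivalent deletions
        equivalents = brute_force_deletions(ref.cds_seq, mut)
        assert (v.start, v.end) == max(equivalents)

    def test_identical_returns_none(self, tiny_cds):
        assert name_variant(tiny_cds, tiny_cds.cds_seq) is None

    def test_single_substitution(self):
        ref = CdsModel("ATGAAACCCTAA")
        v = name_variant(ref, "ATGAAAGCCTAA")
        assert format_hgvs(v) == "c.7C>G"

    def test_duplication_named_dup(self):
        ref = CdsModel("ATGAAACCCTAA")
        v = name_variant(ref, "ATGAAAACCCTAA")
        assert v.kind == "duplication"
        assert format_hgvs(v) == "c.6dup"

    def test_inversion_recognised(self):
        ref = CdsModel("ATGAAACCCGGGTAA")
        mut = apply_variant(ref, parse_hgvs_c("c.4_9inv"))
        v = name_variant(ref, mut)
        assert v.kind == "inversion" and (v.start, v.end) == (4, 9)

    def test_disjoint_edits_rejected(self):
        ref = CdsModel("ATG" + "AAC" * 20 + "TAA")
        seq = ref.cds_seq
        mut = seq[:5] + "G" + seq[6:40] + "T" + seq[41:]
        assert mut != seq and len(mut) == len(seq)
        with pytest.raises(MultipleEditsError):
            name_variant(ref, mut)


def _random_invariant(rng, cds_len: int) -> HgvsVariant:
    kind = rng.choice(["substitution", "deletion", "insertion", "delins", "inversion"])
    bases = "ACGT"
    if kind == "substitution":
        start = int(rng.integers(1, cds_len + 1))
        return ("sub", start)
    if kind == "deletion":
        start = int(rng.integers(1, cds_len - 3))
        end = start + int(rng.integers(0, 5))
        return HgvsVariant("deletion", start, end if end > start else None)
    if kind == "insertion":
        start = int(rng.integers(1, cds_len))
        ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 5))))
        return HgvsVariant("insertion", start, start + 1, insert=ins)
    if kind == "inversion":
        start = int(rng.integers(1, cds_len - 4))
        return HgvsVariant("inversion", start, start + int(rng.integers(1, 5)))
    start = int(rng.integers(1, cds_len - 5))
    end = start + int(rng.integers(0, 4))
    ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 6))))
    return HgvsVariant("delins", start, end if end > start else None, insert=ins)


class TestRoundTrip:
    def test_apply_name_roundtrip_500(self):
        """name_variant(apply_variant(v)) re-produces the same mutant
        sequence, and for pure deletions the 3'-most normalised form."""
        rng = np.random.default_rng(20240901)
        from genoscreen.synthetic import make_reference

        ref = make_reference(7, genome_length=3000, cds_length=300, cds_start=1001)
        cds = ref.cds_model()
        n_checked = 0
        while n_checked < 500:
            v = _random_invariant(rng, 300)
            if isinstance(v, tuple):  # substitution: pick a real alt base
                start = v[1]
                refb = cds.cds_seq[start - 1]
                altb = str(rng.choice([b for b in "ACGT" if b != refb]))
                v = HgvsVariant("substitution", start, None, refb, altb)
            mut_full = apply_variant(cds, v)
            mut = mut_full[cds.upstream_len:]
            named = name_variant(cds, mut)
            if named is None:  # e.g. inverting a palindromic span
                assert mut == cds.cds_seq
                n_checked += 1
                continue
            # naming round-trips in sequence space
            assert apply_variant(cds, named)[cds.upstream_len:] == mut
            if v.kind == "deletion":
                equivalents = brute_force_deletions(cds.cds_seq, mut)
                start_end = (named.start, named.span_end)
                assert start_end == max(equivalents), "deletion not 3'-shifted"
            n_checked += 1


def test_revcomp():
    assert revcomp("AAACCC") == "GGGTTT"
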