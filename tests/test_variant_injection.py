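"""Coordinate mapping, CpG-site membership and allele application."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgivarscan import (
    Variant,
    apply_variant,
    genomic_to_local,
    invert_variant,
    is_cpg_site,
    local_to_genomic,
)
from cgivarscan.variant_injection import RefMismatchError, apply_to_promoter
from conftest import make_promoter, random_sequence


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "strand,pos,expected",
    [("+", 10000, 2000), ("+", 8000, 0), ("+", 12000, 4000), ("-", 10005, 1995), ("-", 12000, 0)],
)
def test_genomic_to_local(strand, pos, expected):
    p = make_promoter("A" * 4001, strand=strand, tss=10000)
    assert genomic_to_local(p, pos) == expected


@pytest.mark.parametrize("strand", ["+", "-"])
def test_round_trip_over_whole_window(strand):
    p = make_promoter("A" * 4001, strand=strand, tss=10000)
    for off in range(0, 4001, 97):
        assert genomic_to_local(p, local_to_genomic(p, off)) == off


def test_out_of_window_position_rejected():
    p = make_promoter("A" * 4001, tss=10000)
    with pytest.raises(ValueError):
        genomic_to_local(p, 7999)
    with pytest.raises(ValueError):
        genomic_to_local(p, 12001)


# ---------------------------------------------------------------------------
# CpG membership
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("offset,expected", [(0, False), (1, True), (2, True), (3, False)])
def test_is_cpg_site(offset, expected):
    assert is_cpg_site("ACGT", offset) is expected


def test_is_cpg_site_bounds():
    with pytest.raises(IndexError):
        is_cpg_site("ACGT", 4)


# ---------------------------------------------------------------------------
# allele application
# ---------------------------------------------------------------------------


def test_substitution():
    assert apply_variant("AACGTT", 2, "C", "T") == "AATGTT"


def test_insertion_keeps_flanks():
    seq = "AAAG" + "TTTT"
    out = apply_variant(seq, 3, "G", "GGCGGT")
    assert out == "AAA" + "GGCGGT" + "TTTT"
    assert len(out) - len(seq) == 5


def test_deletion_with_dash_allele():
    ref = "TCCCCCGCCGCCCC"
    seq = "AAA" + ref + "GGG"
    out = apply_variant(seq, 3, ref, "-")
    assert out == "AAAGGG"
    assert len(out) - len(seq) == -14


def test_ref_mismatch_reports_expected_and_observed():
    with pytest.raises(RefMismatchError, match="expected 'G', found 'C'"):
        apply_variant("AACGTT", 2, "G", "T")


def test_variant_kind_derivation():
    assert Variant("r", "c", 5, "C", "T").kind == "substitution"
    assert Variant("r", "c", 5, "G", "GGCGGT").kind == "insertion"
    assert Variant("r", "c", 5, "TCC", "-").kind == "deletion"
    assert Variant("r", "c", 5, "AT", "GC").kind == "mnv"
    assert Variant("r", "c", 5, "TCC", "-").net_length_change == -3


def test_variant_validation():
    with pytest.raises(ValueError):
        Variant("r", "c", 0, "C", "T")
    with pytest.raises(ValueError):
        Variant("r", "c", 5, "X", "T")


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_apply_invert_round_trip(seed):
    """Seeded apply/invert round trips restore the original exactly, indels included."""
    rng = np.random.default_rng(seed)
    seq = random_sequence(rng, 300)
    offset = int(rng.integers(0, 250))
    kind = rng.choice(["sub", "ins", "del"])
    if kind == "sub":
        ref = seq[offset]
        alt = rng.choice([b for b in "ACGT" if b != ref])
    elif kind == "ins":
        ref = seq[offset]
        alt = ref + "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 8))))
    else:
        ref = seq[offset : offset + int(rng.integers(1, 15))]
        alt = "-"
    mutated = apply_variant(seq, offset, ref, alt)
    assert invert_variant(mutated, offset, ref, alt) == seq


def test_apply_changes_only_the_locus():
    rng = np.random.default_rng(3)
    seq = random_sequence(rng, 500)
    out = apply_variant(seq, 200, seq[200:205], "-")
    assert out[:200] == seq[:200] and out[200:] == seq[205:]


def test_minus_strand_injection_reverse_complements_alleles():
    seq = ("ACGT" * 1001)[:4001]
    p = make_promoter(seq, strand="-", tss=10000)
    # stored base at offset 1000 is 'A'; on the + genomic strand that is 'T'
    v = Variant("rs", "chr1", 12000 - 1000, "T", "G")
    var_seq, offset, ref, alt = apply_to_promoter(p, v)
    assert (offset, ref, alt) == (1000, "A", "C")
    assert var_seq[1000] == "C"
    assert sum(a != b for a, b in zip(seq, var_seq)) == 1
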