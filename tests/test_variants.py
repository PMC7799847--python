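from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from brcascreen.variants import (
    BRCA1_REGION,
    GenomicVariant,
    NormalizationError,
    ReferenceWindow,
    RegionSpec,
    TrimmedVariant,
    VcfError,
    extract_region,
    from_trimmed,
    normalize,
    read_sites_vcf,
    split_multiallelic,
    to_trimmed,
    write_sites_vcf,
)
from oracles import apply_edit, minimal_leftmost_representation

BASES = "ACGT"


# ---------------------------------------------------------------------------
# construction invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(chrom="13", pos=0, ref="A", alt="T"),
        dict(chrom="13", pos=5, ref="A", alt="A"),
        dict(chrom="13", pos=5, ref="", alt="T"),
        dict(chrom="13", pos=5, ref="A", alt="T", af={"x": 1.5}),
    ],
)
def test_genomic_variant_rejects_invalid(kwargs):
    with pytest.raises(ValueError):
        GenomicVariant(**kwargs)


def test_chromosome_prefix_is_stripped():
    assert GenomicVariant("chr17", 10, "A", "T").chrom == "17"
    assert RegionSpec("chr13", 1, 5).chrom == "13"


def test_trimmed_variant_rejects_double_dash_and_bad_span():
    with pytest.raises(ValueError):
        TrimmedVariant("13", 5, 5, "-", "-")
    with pytest.raises(ValueError):
        TrimmedVariant("13", 5, 4, "AG", "-")


# ---------------------------------------------------------------------------
# multi-allelic splitting
# ---------------------------------------------------------------------------

def test_split_pairs_alts_with_afs():
    recs = split_multiallelic("13", 100, "G", ["A", "T"], [0.01, 0.002], "panel")
    assert [(r.alt, r.af["panel"]) for r in recs] == [("A", 0.01), ("T", 0.002)]
    assert all(r.pos == 100 and r.ref == "G" for r in recs)


def test_split_biallelic_is_identity():
    (rec,) = split_multiallelic("13", 100, "G", ["A"], [0.01])
    assert (rec.chrom, rec.pos, rec.ref, rec.alt) == ("13", 100, "G", "A")


def test_split_three_alts_matches_independent_index_parse():
    alts, afs = ["A", "T", "GTT"], [0.1, 0.01, 0.001]
    recs = split_multiallelic("13", 7, "G", alts, afs, "x")
    for i, rec in enumerate(recs):
        assert rec.alt == alts[i] and rec.af["x"] == afs[i]


def test_split_errors():
    with pytest.raises(VcfError):
        split_multiallelic("13", 7, "G", [])
    with pytest.raises(VcfError):
        split_multiallelic("13", 7, "G", ["A", "T"], [0.1])


@given(
    st.lists(
        st.tuples(st.sampled_from(["A", "T", "GG", "GTT"]), st.floats(0, 0.5)),
        min_size=1,
        max_size=4,
        unique_by=lambda t: t[0],
    )
)
def test_split_conserves_alt_count_and_af_multiset(pairs):
    alts = [a for a, _ in pairs]
    afs = [f for _, f in pairs]
    recs = split_multiallelic("1", 50, "C", alts, afs, "d")
    assert len(recs) == len(alts)
    assert sorted(r.af["d"] for r in recs) == sorted(afs)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _window(seq: str) -> ReferenceWindow:
    return ReferenceWindow("1", seq)


def test_snv_already_minimal():
    seq = "ACGTACGTAC"
    v = GenomicVariant("1", 3, "G", "T")
    assert normalize(v, _window(seq)) == v


def test_mnv_trims_shared_suffix():
    # shared trailing G: AG>CG at pos 5 reduces to the SNV A>C
    seq = "TTTTAGTT"
    v = normalize(GenomicVariant("1", 5, "AG", "CG"), _window(seq))
    assert (v.pos, v.ref, v.alt) == (5, "A", "C")
    assert (5, "A", "C") == minimal_leftmost_representation(seq, 5, "AG", "CG")


def test_deletion_left_aligns_through_homopolymer():
    seq = "GGTAAAAC"
    v = normalize(GenomicVariant("1", 6, "AA", "A"), _window(seq))
    assert (v.pos, v.ref, v.alt) == (3, "TA", "T")
    assert (3, "TA", "T") == minimal_leftmost_representation(seq, 6, "AA", "A")


def test_normalize_errors():
    seq = "ACGTACGT"
    with pytest.raises(NormalizationError, match="disagrees"):
        normalize(GenomicVariant("1", 2, "A", "T"), _window(seq))
    # deletion in a homopolymer starting at the window edge cannot left-align
    with pytest.raises(NormalizationError, match="window"):
        normalize(GenomicVariant("1", 3, "AA", "A"), ReferenceWindow("1", "AAA", offset=2))


@st.composite
def sequence_and_edit(draw):
    seq = "".join(draw(st.lists(st.sampled_from(BASES), min_size=20, max_size=60)))
    pos = draw(st.integers(5, len(seq) - 6))
    kind = draw(st.sampled_from(["snv", "del", "ins", "mnv"]))
    if kind == "snv":
        ref = seq[pos - 1]
        alt = draw(st.sampled_from([b for b in BASES if b != ref]))
    elif kind == "del":
        length = draw(st.integers(1, 4))
        ref = seq[pos - 1 : pos + length]
        alt = ref[0]
    elif kind == "ins":
        ref = seq[pos - 1]
        alt = ref + "".join(draw(st.lists(st.sampled_from(BASES), min_size=1, max_size=4)))
    else:
        length = draw(st.integers(2, 4))
        ref = seq[pos - 1 : pos - 1 + length]
        alt = "".join(draw(st.lists(st.sampled_from(BASES), min_size=length, max_size=length)))
        if alt == ref:
            alt = alt[:-1] + ("A" if ref[-1] != "A" else "C")
    return seq, pos, ref, alt


@given(sequence_and_edit())
def test_normalize_matches_brute_force_and_preserves_haplotype(case):
    seq, pos, ref, alt = case
    v = normalize(GenomicVariant("1", pos, ref, alt), _window(seq))
    # haplotype equivalence
    assert apply_edit(seq, v.pos, v.ref, v.alt) == apply_edit(seq, pos, ref, alt)
    # minimal leftmost representation, per exhaustive enumeration
    assert (v.pos, v.ref, v.alt) == minimal_leftmost_representation(seq, pos, ref, alt)
    # idempotence
    assert normalize(v, _window(seq)) == v


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------

def test_region_boundaries_inclusive():
    inside = GenomicVariant("17", 41_196_312, "A", "T")
    outside = GenomicVariant("17", 41_196_311, "A", "T")
    kept = extract_region([inside, outside], BRCA1_REGION)
    assert kept == [inside]


def test_region_extraction_matches_naive_loop(rng):
    region = RegionSpec("13", 500, 1500)
    variants = [
        GenomicVariant(str(rng.choice(["13", "17"])), int(p), "A", "T")
        for p in rng.integers(1, 2500, size=100)
    ]
    kept = extract_region(variants, region)
    naive = [
        v
        for v in variants
        if v.chrom == "13" and 500 <= v.pos <= 1500
    ]
    assert kept == naive
    # partition property
    out = [v for v in variants if v not in kept]
    assert len(kept) + len(out) == len(variants)


# ---------------------------------------------------------------------------
# trimmed-coordinate conversion
# ---------------------------------------------------------------------------

def test_snv_to_trimmed_keeps_coordinates():
    v = GenomicVariant("13", 32_920_978, "C", "T")
    assert to_trimmed(v) == TrimmedVariant("13", 32_920_978, 32_920_978, "C", "T")


def test_deletion_to_trimmed_drops_anchor():
    v = GenomicVariant("13", 32_903_604, "ATG", "A")
    assert to_trimmed(v) == TrimmedVariant("13", 32_903_605, 32_903_606, "TG", "-")


def test_insertion_from_trimmed_uses_anchor_base():
    # window anchored at the insertion locus supplies the anchor base
    win = ReferenceWindow("13", "G", offset=32_890_626)
    t = TrimmedVariant("13", 32_890_627, 32_890_627, "-", "T")
    v = from_trimmed(t, win)
    assert (v.pos, v.ref, v.alt) == (32_890_627, "G", "GT")
    assert to_trimmed(v) == t


def test_snv_from_trimmed_is_identity():
    t = TrimmedVariant("17", 100, 100, "G", "A")
    v = from_trimmed(t, ReferenceWindow("17", ""))
    assert (v.pos, v.ref, v.alt) == (100, "G", "A")


def test_to_trimmed_rejects_unnormalized():
    with pytest.raises(ValueError, match="not normalized"):
        to_trimmed(GenomicVariant("13", 5, "ATG", "AGG"))


def test_from_trimmed_anchor_unavailable():
    t = TrimmedVariant("13", 10, 12, "CCC", "-")
    with pytest.raises(NormalizationError, match="anchor"):
        from_trimmed(t, ReferenceWindow("13", "A", offset=100))


def test_trimmed_round_trip_on_random_indels(rng):
    seq = "".join(rng.choice(list(BASES), size=300))
    win = ReferenceWindow("13", seq)
    for _ in range(50):
        pos = int(rng.integers(5, 290))
        if rng.random() < 0.5:
            ref = seq[pos - 1 : pos - 1 + int(rng.integers(2, 5))]
            alt = ref[0]
        else:
            ref = seq[pos - 1]
            alt = ref + "".join(rng.choice(list(BASES), size=int(rng.integers(1, 4))))
        v = normalize(GenomicVariant("13", pos, ref, alt), win)
        assert from_trimmed(to_trimmed(v), win) == v


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def test_sites_vcf_round_trip(tmp_path, rng):
    variants = [
        GenomicVariant("13", 100, "A", "T", {"panel": 0.25}),
        GenomicVariant("13", 200, "G", "GTT", {"panel": 0.5}),
        GenomicVariant("13", 300, "CAA", "C"),
        GenomicVariant("17", 150, "C", "G", {"panel": 0.125}),
        GenomicVariant("17", 400, "T", "A", {"panel": 0.0625}),
    ]
    path = tmp_path / "sites.vcf"
    write_sites_vcf(path, variants, dataset_tag="panel")
    back = read_sites_vcf(path, dataset_tag="panel")
    assert back == variants  # identity over (chrom, pos, ref, alt)
    # AF round-trips through the VCF float field; missing stays missing
    assert back[0].af["panel"] == pytest.approx(0.25)
    assert back[2].af == {}


def test_multiallelic_site_is_split_with_af_pairing(tmp_path):
    path = tmp_path / "multi.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
        "##contig=<ID=13>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "13\t100\t.\tG\tA,T\t.\t.\tAF=0.01,0.002\n"
    )
    recs = read_sites_vcf(path, dataset_tag="d")
    assert [(r.alt, pytest.approx(r.af["d"], rel=1e-5)) for r in recs] == [
        ("A", 0.01),
        ("T", 0.002),
    ]


def test_malformed_vcf_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=13>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "13\t100\t.\tG\t.\t.\t.\t.\n"  # missing ALT
    )
    with pytest.raises(VcfError, match="line 4"):
        read_sites_vcf(path)
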