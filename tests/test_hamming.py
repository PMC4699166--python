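"""Variant encoding, padding, the distance rule, and all four schemes."""

import itertools
import math
import random

import pytest

from genoshare.hamming import (
    EncodedRecord,
    EncodedSet,
    EncodingError,
    EncodingParams,
    PaddingError,
    VariantRecord,
    dummy_record,
    encode_record,
    encode_string,
    filter_records,
    hamming_distance,
    hd_clear,
    pad_dummies,
    padded_sizes_pow2,
    transform_locations,
)
from genoshare.synth import SynthVcfSpec, synth_vcf_pair

SCHEMES = ("basic", "split", "newmerge", "full")


def vr(chrom, pos, ref, alt, svtype):
    return VariantRecord(chrom=str(chrom), pos=pos, ref=ref, alt=alt,
                         svtype=svtype)


# ---------------------------------------------------------------------------
# filtering and the cleartext rule


def test_filter_keeps_sub_and_snp_in_order():
    rs = [vr(1, 10, "A", "C", "SNP"), vr(1, 20, "AT", "A", "DEL"),
          vr(1, 30, "AC", "GT", "SUB"), vr(1, 40, "A", "AT", "INS")]
    kept = filter_records(rs)
    assert [r.svtype for r in kept] == ["SNP", "SUB"]
    assert filter_records([vr(1, i, "AT", "A", "DEL") for i in range(3)]) == []


def test_hd_clear_identical_sets_zero():
    rs = [vr(1, 10, "A", "C", "SNP"), vr(2, 5, "ACG", "T", "SUB")]
    assert hd_clear(rs, list(rs)) == 0


def test_hd_clear_disjoint_counts_everything():
    r1 = [vr(1, i, "A", "C", "SNP") for i in range(1, 6)]
    r2 = [vr(2, i, "A", "G", "SNP") for i in range(1, 4)]
    assert hd_clear(r1, r2) == 8


@pytest.mark.parametrize("ref2,alt2,expect", [
    ("A", "G", 1),   # REF equal, ALT differs -> counts
    ("C", "G", 0),   # REF differs -> does not count
    ("A", "C", 0),   # identical record -> does not count
])
def test_hd_clear_shared_location_rule(ref2, alt2, expect):
    r1 = [vr(1, 100, "A", "C", "SNP")]
    r2 = [vr(1, 100, ref2, alt2, "SNP")]
    assert hd_clear(r1, r2) == expect


def test_hd_clear_rejects_duplicate_locations():
    r1 = [vr(1, 5, "A", "C", "SNP"), vr(1, 5, "AC", "G", "SUB")]
    with pytest.raises(ValueError, match="duplicate"):
        hd_clear(r1, [])


# ---------------------------------------------------------------------------
# encoding


def test_location_encoding_formula():
    p = EncodingParams()
    r = encode_record(vr(1, 100, "A", "C", "SNP"), "SUB_full", p)
    assert r.v1 == 250_000_100
    assert encode_record(vr("X", 7, "A", "C", "SNP"), "SUB_full", p).v1 == \
        23 * p.L + 7


def test_string_encoding_hand_examples():
    p = EncodingParams(M=2)
    assert p.len_bits == 2
    assert encode_string("A", p) == 0b000001       # 0000 || 01
    assert encode_string("AC", p) == 0b000110      # 0001 || 10


def test_string_encoding_injective_small_m():
    p = EncodingParams(M=3)
    strings = ["".join(s) for n in (1, 2, 3)
               for s in itertools.product("ACGT", repeat=n)]
    codes = [encode_string(s, p) for s in strings]
    assert len(set(codes)) == len(codes)


def test_encoding_errors():
    p = EncodingParams(M=2)
    with pytest.raises(EncodingError, match="length"):
        encode_string("ACG", p)
    with pytest.raises(EncodingError, match="nucleotide"):
        encode_string("AN", p)
    with pytest.raises(EncodingError, match="chromosome"):
        encode_record(vr("MT", 5, "A", "C", "SNP"), "SUB_full", p)


def test_compact_encoding():
    p = EncodingParams(M=5)
    r = encode_record(vr(1, 9, "G", "T", "SNP"), "SNPSUB_compact", p)
    assert (r.v2, r.v3, r.v4) == (2, 3, 1)
    r2 = encode_record(vr(1, 9, "GAT", "T", "SUB"), "SNPSUB_compact", p)
    assert (r2.v2, r2.v3, r2.v4) == (4, 3, 0)


def test_dummy_records_sort_last():
    p = EncodingParams()
    d = dummy_record("full", p)
    assert d.v1 == 25 * p.L + 1
    assert (d.v2, d.v3, d.is_dummy) == (0, 0, True)
    assert d.v1 > 24 * p.L + p.L  # beyond any real location


# ---------------------------------------------------------------------------
# padding and the location transform


def test_padded_sizes_basic_example():
    t1, t2, q = padded_sizes_pow2(5, 8, 1.0)
    assert q == 4 and t1 + t2 == 16


def test_padded_sizes_formula_oracle():
    rng = random.Random(50)
    for _ in range(50):
        n1, n2 = rng.randrange(1, 300), rng.randrange(1, 300)
        frac = rng.choice([1.0, 0.3, 0.5])
        t1, t2, q = padded_sizes_pow2(n1, n2, frac)
        assert t1 + t2 == 1 << q
        assert q == math.ceil(math.log2(frac * n1 + frac * n2 + 2))
        assert t2 == math.floor(frac * n2) + 1


def test_pad_dummies_newmerge_size_and_error():
    p = EncodingParams(M=2)
    enc = [encode_record(vr(1, i, "A", "C", "SNP"), "SUB_full", p)
           for i in (5, 2, 9, 1, 4)]
    es = pad_dummies(enc, 6, "full", p)
    assert len(es.records) == 6 and es.d == 1
    assert [r.v1 for r in es.records] == sorted(r.v1 for r in es.records)
    with pytest.raises(PaddingError):
        pad_dummies(enc, 5, "full", p)


def test_transform_locations_separates_copies_from_matches():
    p = EncodingParams(M=2)
    es = EncodedSet([EncodedRecord(10, 0, 0)], d=1, mode="full")
    assert transform_locations(es, 1).records[0].v1 == 40
    assert transform_locations(es, 2).records[0].v1 == 41
    for v, w in itertools.product(range(100), repeat=2):
        assert (abs(4 * v - (4 * w + 1)) == 1) == (v == w)


# ---------------------------------------------------------------------------
# schemes vs the oracle


def _pair(seed, **kw):
    spec = SynthVcfSpec(seed=seed, **kw)
    return synth_vcf_pair(spec)


@pytest.mark.parametrize("scheme", SCHEMES)
def test_scheme_matches_oracle_on_random_pairs(scheme):
    for seed in range(8):
        pair = _pair(seed, n1=14, n2=11, overlap=0.4,
                     type_mismatch_fraction=0.25)
        run = hamming_distance(pair.records1, pair.records2, scheme=scheme,
                               backend="cleartext")
        assert run.distance == pair.truth


@pytest.mark.parametrize("scheme", SCHEMES)
def test_scheme_secure_backend_matches_oracle(scheme):
    pair = _pair(60, n1=9, n2=12, overlap=0.5, type_mismatch_fraction=0.2)
    run = hamming_distance(pair.records1, pair.records2, scheme=scheme,
                           backend="secure", seed=61)
    assert run.distance == pair.truth


def test_type_mismatch_pair_counts_correctly():
    """A location typed SUB in one set and SNP in the other must contribute
    per the REF/ALT rule, not 2 (the split double count)."""
    fill1 = [vr(3, 10 + i, "A", "G", "SNP") for i in range(3)]
    fill2 = [vr(4, 10 + i, "C", "T", "SNP") for i in range(3)]
    base1 = [vr(2, 50, "A", "C", "SUB")] + fill1
    for alt2, expect in (("C", 6), ("G", 7)):
        r2 = [vr(2, 50, "A", alt2, "SNP")] + fill2
        assert hd_clear(base1, r2) == expect
        for scheme in ("split", "full"):
            run = hamming_distance(base1, r2, scheme=scheme,
                                   backend="cleartext")
            assert run.distance == expect, (scheme, alt2)


def test_full_scheme_without_sub_records():
    r1 = [vr(1, i, "A", "C", "SNP") for i in (3, 8, 15)]
    r2 = [vr(1, i, "A", "G", "SNP") for i in (8, 21)]
    want = hd_clear(r1, r2)
    run = hamming_distance(r1, r2, scheme="full", backend="cleartext")
    assert run.distance == want


def test_sizes_just_above_power_of_two():
    pair = _pair(62, n1=17, n2=16, overlap=0.5, irrelevant_fraction=0.0)
    for scheme in SCHEMES:
        run = hamming_distance(pair.records1, pair.records2, scheme=scheme,
                               backend="cleartext")
        assert run.distance == pair.truth


def test_extra_dummies_do_not_change_distance():
    """Appending irrelevant (filtered-out) records inflates the public sizes
    and hence the dummy counts, but never the distance."""
    pair = _pair(63, n1=10, n2=8, overlap=0.5, irrelevant_fraction=0.0)
    extra1 = pair.records1 + [vr(9, 999 + i, "AT", "A", "DEL")
                              for i in range(3)]
    extra2 = pair.records2 + [vr(9, 1999 + i, "A", "AT", "INS")
                              for i in range(5)]
    for scheme in SCHEMES:
        run = hamming_distance(extra1, extra2, scheme=scheme,
                               backend="cleartext")
        assert run.distance == pair.truth


def test_distance_symmetry_and_bounds():
    for seed in range(5):
        pair = _pair(70 + seed, n1=12, n2=9, overlap=0.6)
        n1 = len(filter_records(pair.records1))
        n2 = len(filter_records(pair.records2))
        assert 0 <= pair.truth <= n1 + n2
        swapped = hamming_distance(pair.records2, pair.records1,
                                   scheme="full", backend="cleartext")
        assert swapped.distance == pair.truth


def test_block_partition_used_for_wide_strings():
    """Default M=100 encodings exceed one modulus word and are compared
    block-wise; results still match the oracle."""
    p = EncodingParams()  # M = 100: 207-bit V2/V3 -> 3 blocks under 118 bits
    assert p.string_bits == 207
    r1 = [vr(1, 5, "A" * 60, "C" * 60, "SUB"), vr(1, 9, "A", "C", "SNP")]
    r2 = [vr(1, 5, "A" * 60, "G" * 60, "SUB"), vr(1, 11, "A", "C", "SNP")]
    want = hd_clear(r1, r2)  # shared loc: REF equal, ALT differs -> 1 (+2)
    assert want == 3
    run = hamming_distance(r1, r2, scheme="basic", backend="secure",
                           params=p, seed=64)
    assert run.distance == want
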