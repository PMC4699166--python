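"""Secure genomic Hamming distance over VCF-derived variant records.

The distance between two variant sets counts, over records of type SUB or
SNP only: +1 for every location <CHROM, POS> present in exactly one set,
and +1 for every shared location whose REF fields agree while the ALT
fields differ.  ``hd_clear`` evaluates this rule directly and serves as the
oracle for the oblivious schemes.

The oblivious pipeline encodes each record as integers

* V1 = chrom_index * L + pos            (location key; dummies get 25L + 1)
* V2, V3 = REF / ALT as packed 2-bit nucleotide strings, zero-padded to the
  public maximum length M with the character count appended so that
  distinct strings (including prefixes) always encode distinctly
* V4 = 1 for SNP records, 0 otherwise   (compact SNP&SUB sets only)

pads with dummy records to a public size, secret-shares everything, merges
the two sorted sets obliviously, and scans adjacent pairs with batched
equality tests.  Four schemes are provided:

* ``basic``     — power-of-two padding, single wide modulus
* ``split``     — SUB records and SNP&SUB records processed separately
  (compact 3-bit REF/ALT codes for the latter under a narrower modulus),
  with the double-count of locations typed SUB in one set and SNP in the
  other compensated in-protocol; the two sub-distances are combined after a
  cross-modulus share conversion
* ``newmerge``  — generalised merge for arbitrary sizes (padding only to
  N_i + 1); the location transform 4*V1 / 4*V1 + 1 makes genuine cross-set
  equal-location pairs differ by exactly 1 while merge-introduced duplicate
  copies keep distance 0
* ``full``      — both optimisations combined

Wide REF/ALT encodings whose bitlength exceeds what the modulus can mask
are partitioned into equal blocks compared block-wise and AND-ed together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .merge import KeyedRecord, batcher_merge, new_merge
from .primitives import Backend, make_backend
from .sharing import (
    HAMMING_LARGE_MODULUS_BITS,
    HAMMING_SMALL_MODULUS_BITS,
    MpcContext,
    smallest_prime_above,
)

SVTYPES = ("SUB", "SNP", "DEL", "INS")
_NUC = {"A": 0, "C": 1, "G": 2, "T": 3}

CHROM_INDEX = {**{str(i): i for i in range(1, 23)}, "X": 23, "Y": 24}


class EncodingError(ValueError):
    pass


class PaddingError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """One VCF record reduced to the fields the distance rule consumes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    svtype: str

    def __post_init__(self):
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")


@dataclass(frozen=True)
class EncodingParams:
    """Public encoding constants.

    ``L`` exceeds the longest human chromosome so that V1 = chrom*L + pos is
    injective on locations; ``M`` bounds REF/ALT string length; ``alpha``
    and ``alpha_s`` are the public maximum fractions of SUB&SNP and of SUB
    records used for padding targets.
    """

    L: int = 250_000_000
    M: int = 100
    alpha: float = 1.0
    alpha_s: float = 0.3

    @property
    def len_bits(self) -> int:
        return max(1, math.ceil(math.log2(self.M + 1)))

    @property
    def string_bits(self) -> int:
        return 2 * self.M + self.len_bits

    @property
    def dummy_v1(self) -> int:
        return 25 * self.L + 1

    @property
    def key_bits(self) -> int:
        return self.dummy_v1.bit_length()

    @property
    def transformed_key_bits(self) -> int:
        return (4 * self.dummy_v1 + 1).bit_length()


@dataclass(frozen=True)
class EncodedRecord:
    v1: int
    v2: int
    v3: int
    v4: int | None = None
    is_dummy: bool = False


@dataclass
class EncodedSet:
    """Sorted, dummy-padded encoded records of one input site."""

    records: list[EncodedRecord]
    d: int          # dummy count (secret in the protocols)
    mode: str       # "full" or "compact"

    def __post_init__(self):
        if self.d < 1:
            raise PaddingError("at least one dummy record is required")


# ---------------------------------------------------------------------------
# cleartext side


def filter_records(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep SUB and SNP records, preserving input order."""
    return [r for r in records if r.svtype in ("SUB", "SNP")]


def _location_map(records: Sequence[VariantRecord]) -> dict:
    m = {}
    for r in filter_records(records):
        key = (r.chrom, r.pos)
        if key in m:
            raise ValueError(f"duplicate location {key} within one dataset")
        m[key] = r
    return m


def hd_clear(S1: Sequence[VariantRecord], S2: Sequence[VariantRecord],
             branch_hits: dict | None = None) -> int:
    """The reference distance rule evaluated in the clear.

    ``branch_hits`` (optional dict) accumulates how often each rule branch
    fired, letting generators prove their instances exercise every branch.
    """
    m = _location_map(S1)
    _location_map(S2)  # duplicate check for the second set as well
    hits = branch_hits if branch_hits is not None else {}
    hits.setdefault("only_s1", 0)
    hits.setdefault("only_s2", 0)
    hits.setdefault("shared_ref_eq_alt_ne", 0)
    hits.setdefault("shared_other", 0)
    dist = len(m)
    matched = set()
    for r in filter_records(S2):
        key = (r.chrom, r.pos)
        if key not in m:
            dist += 1
            hits["only_s2"] += 1
        else:
            matched.add(key)
            dist -= 1
            other = m[key]
            if other.ref == r.ref and other.alt != r.alt:
                dist += 1
                hits["shared_ref_eq_alt_ne"] += 1
            else:
                hits["shared_other"] += 1
    hits["only_s1"] += len(m) - len(matched)
    return dist


def encode_string(s: str, params: EncodingParams) -> int:
    """Pack a nucleotide string into 2M bits (left-justified, zero padding)
    followed by its character count; injective up to length M."""
    if not (1 <= len(s) <= params.M):
        raise EncodingError(f"string length {len(s)} outside [1, M={params.M}]")
    code = 0
    for ch in s:
        if ch not in _NUC:
            raise EncodingError(f"non-nucleotide character {ch!r}")
        code = (code << 2) | _NUC[ch]
    code <<= 2 * (params.M - len(s))
    return (code << params.len_bits) | len(s)


def encode_record(r: VariantRecord, mode: str,
                  params: EncodingParams) -> EncodedRecord:
    """Integer encoding of one record.

    ``SUB_full`` keeps full-width REF/ALT codes; ``SNPSUB_compact`` maps
    single characters to 0-3 and longer strings to 4, and carries the type
    bit V4 (SNP = 1).
    """
    if r.chrom not in CHROM_INDEX:
        raise EncodingError(f"chromosome {r.chrom!r} outside 1-22, X, Y")
    if r.pos < 1 or r.pos > params.L:
        raise EncodingError(f"position {r.pos} outside [1, L]")
    v1 = CHROM_INDEX[r.chrom] * params.L + r.pos
    if mode == "SUB_full":
        return EncodedRecord(v1, encode_string(r.ref, params),
                             encode_string(r.alt, params))
    if mode == "SNPSUB_compact":
        def compact(s: str) -> int:
            if len(s) == 1:
                if s not in _NUC:
                    raise EncodingError(f"non-nucleotide character {s!r}")
                return _NUC[s]
            if len(s) > params.M:
                raise EncodingError("string longer than M")
            return 4
        return EncodedRecord(v1, compact(r.ref), compact(r.alt),
                             v4=int(r.svtype == "SNP"))
    raise ValueError(f"unknown encoding mode {mode!r}")


def dummy_record(mode: str, params: EncodingParams) -> EncodedRecord:
    v4 = None if mode in ("full", "SUB_full") else 0
    return EncodedRecord(params.dummy_v1, 0, 0, v4=v4, is_dummy=True)


def transform_locations(eset: EncodedSet, site: int,
                        params: EncodingParams | None = None) -> EncodedSet:
    """Location spreading for the generalised merge: site 1 keys become
    4*V1, site 2 keys 4*V1 + 1.  Cross-site records at the same original
    location then differ by exactly 1 and all other pairs by at least 3.
    In the protocols this is applied to shares by public-constant scaling.
    """
    if site not in (1, 2):
        raise ValueError("site must be 1 or 2")
    off = site - 1
    recs = [EncodedRecord(4 * r.v1 + off, r.v2, r.v3, r.v4, r.is_dummy)
            for r in eset.records]
    return EncodedSet(recs, eset.d, eset.mode)


# ---------------------------------------------------------------------------
# padding


def _q_for(count: float) -> int:
    return math.ceil(math.log2(count))


def padded_sizes_pow2(N1: int, N2: int, frac: float) -> tuple[int, int, int]:
    """Per-site padded sizes summing to 2**q, q = ceil(log2(frac*(N1+N2)+2)).

    Each site first pads to floor(frac*N_i) + 1; the remainder of the
    power-of-two budget goes to site 1 (a public convention).
    """
    q = _q_for(frac * N1 + frac * N2 + 2)
    base1 = math.floor(frac * N1) + 1
    base2 = math.floor(frac * N2) + 1
    extra = (1 << q) - base1 - base2
    if extra < 0:
        raise PaddingError("power-of-two budget smaller than per-site targets")
    return base1 + extra, base2, q


def pad_dummies(encoded: Sequence[EncodedRecord], target_size: int, mode: str,
                params: EncodingParams) -> EncodedSet:
    """Sort real records by V1 and append dummies up to ``target_size``.

    Dummies carry V1 = 25L + 1 and therefore sort after every real record.
    At least one dummy is always present; a target smaller than the real
    count + 1 raises :class:`PaddingError` (e.g. alpha_s underestimating
    the SUB fraction).
    """
    real = sorted(encoded, key=lambda r: r.v1)
    d = target_size - len(real)
    if d < 1:
        raise PaddingError(
            f"cannot pad {len(real)} records to {target_size} with >=1 dummy")
    return EncodedSet(real + [dummy_record(mode, params)] * d, d, mode)


# ---------------------------------------------------------------------------
# shared-set plumbing


def _n_blocks(total_bits: int, ctx: MpcContext) -> int:
    cap = ctx.p.bit_length() - ctx.kappa - 3
    if cap < 8:
        raise ValueError("modulus too small for any block size")
    return max(1, math.ceil(total_bits / cap))


def _split_blocks(value: int, total_bits: int, n_blocks: int) -> list[int]:
    bb = math.ceil(total_bits / n_blocks)
    mask = (1 << bb) - 1
    return [(value >> (bb * (n_blocks - 1 - i))) & mask for i in range(n_blocks)]


@dataclass
class SharedSet:
    """One site's encoded set after sharing: merge-ready keyed records plus
    the shared dummy count."""

    records: list[KeyedRecord]
    d_shared: object
    n_blocks: int
    block_bits: int


def share_encoded_set(be: Backend, eset: EncodedSet, params: EncodingParams,
                      transform_site: int | None = None) -> SharedSet:
    """Secret-share an encoded set column-wise.

    In full mode V2/V3 are split into equal blocks sized to the modulus;
    payload layout is (v2 blocks..., v3 blocks...) or (v2, v3, v4) in
    compact mode.  ``transform_site`` applies the 4*V1 (+1) location
    transform to the shared keys by local public scaling.
    """
    recs = eset.records
    v1 = be.input_vec([r.v1 for r in recs])
    if transform_site is not None:
        v1 = be.affine_vec(v1, 4, transform_site - 1)
    if eset.mode == "full":
        nb = _n_blocks(params.string_bits, be.ctx)
        bb = math.ceil(params.string_bits / nb)
        cols = []
        for i in range(nb):
            cols.append(be.input_vec(
                [_split_blocks(r.v2, params.string_bits, nb)[i] for r in recs]))
        for i in range(nb):
            cols.append(be.input_vec(
                [_split_blocks(r.v3, params.string_bits, nb)[i] for r in recs]))
        payload_cols = cols
    else:
        nb, bb = 1, 3
        payload_cols = [be.input_vec([r.v2 for r in recs]),
                        be.input_vec([r.v3 for r in recs]),
                        be.input_vec([r.v4 for r in recs])]
    keyed = []
    for i, _ in enumerate(recs):
        keyed.append(KeyedRecord(v1[i], tuple(col[i] for col in payload_cols)))
    d_shared = be.input_vec([eset.d])[0]
    return SharedSet(keyed, d_shared, nb, bb)


def _columns(merged: Sequence[KeyedRecord]):
    keys = [r.key for r in merged]
    arity = len(merged[0].payload)
    cols = [[r.payload[i] for r in merged] for i in range(arity)]
    return keys, cols


def _eq_blocks(be: Backend, prev_cols, cur_cols, block_bits: int):
    """AND of per-block equalities (one EQ per block, then a product tree)."""
    bits = [be.eq_vec(pc, cc, block_bits) for pc, cc in zip(prev_cols, cur_cols)]
    while len(bits) > 1:
        nxt = []
        for i in range(0, len(bits) - 1, 2):
            nxt.append(be.mult_vec(bits[i], bits[i + 1]))
        if len(bits) % 2:
            nxt.append(bits[-1])
        bits = nxt
    return bits[0]


def _decode_dist(be: Backend, dist_handle) -> int:
    return be.open_signed_vec([dist_handle])[0]


# ---------------------------------------------------------------------------
# the four schemes


def secure_hd_basic(be: Backend, s1: SharedSet, s2: SharedSet,
                    params: EncodingParams) -> int:
    """Distance over power-of-two padded sets (the basic scheme).

    Adjacent-pair scan of the merged set: a new location adds 1; a repeated
    location retracts the previous add unless REF matches and ALT differs.
    The 2(d1 + d2) - ... dummy surplus is corrected with the shared dummy
    counts at the end.  All loop iterations run in parallel batches.
    """
    ell = params.key_bits
    merged = batcher_merge(be, s1.records, s2.records, ell)
    keys, cols = _columns(merged)
    nb = s1.n_blocks
    prev_k, cur_k = keys[:-1], keys[1:]
    a = be.eq_vec(prev_k, cur_k, ell)
    b = _eq_blocks(be, [c[:-1] for c in cols[:nb]], [c[1:] for c in cols[:nb]],
                   s1.block_bits)
    c = _eq_blocks(be, [c[:-1] for c in cols[nb:]], [c[1:] for c in cols[nb:]],
                   s1.block_bits)
    t = be.sub_vec(b, be.mult_vec(b, c))            # b(1-c)
    u = be.mult_vec(a, be.affine_vec(t, 1, -1))     # a(b(1-c)-1)
    terms = be.add_vec(be.affine_vec(a, -1, 1), u)  # (1-a) + a(...)
    dist = be.total(terms)
    dist = be.add_vec([dist], [s1.d_shared])
    dist = be.add_vec(dist, [s2.d_shared])
    dist = be.affine_vec(dist, 1, -1)  # +1 (first record) - 2 (dummy floor)
    return _decode_dist(be, dist[0])


def _scan_snpsub_pow2(be: Backend, s1: SharedSet, s2: SharedSet,
                      params: EncodingParams) -> object:
    """Shared SNP&SUB distance over a power-of-two merge (compact codes).

    Only pairs containing a SNP record matter; a first sighting counts only
    if it is a SNP, a second sighting retracts only a SNP predecessor, and
    equal-location pairs of different type cancel the double count the SUB
    pass introduced.
    """
    ell = params.key_bits
    merged = batcher_merge(be, s1.records, s2.records, ell)
    keys, (v2, v3, v4) = _columns(merged)
    prev_k, cur_k = keys[:-1], keys[1:]
    v4p, v4c = v4[:-1], v4[1:]
    a = be.eq_vec(prev_k, cur_k, ell)
    b = be.eq_vec(v2[:-1], v2[1:], 3)
    c = be.eq_vec(v3[:-1], v3[1:], 3)
    d, e = be.or_xor_vec(v4p, v4c)
    t = be.sub_vec(b, be.mult_vec(b, c))
    # (1-a)V4_i + a(t - V4_{i-1}) = V4_i + a(t - V4_{i-1} - V4_i)
    inner = be.add_vec(v4c, be.mult_vec(a, be.sub_vec(be.sub_vec(t, v4p), v4c)))
    m2 = be.mult_vec(d, inner)
    m3 = be.mult_vec(a, e)
    terms = be.sub_vec(m2, m3)
    dist = be.total(terms)
    return be.add_vec([dist], [v4[0]])[0]


def secure_hd_split(be_large: Backend, be_small: Backend,
                    s1sub: SharedSet, s2sub: SharedSet,
                    s1ss: SharedSet, s2ss: SharedSet,
                    params: EncodingParams) -> int:
    """SUB/SNP separated scheme: wide-modulus pass over SUB sets plus a
    narrow-modulus pass over SNP&SUB sets, combined across moduli."""
    ell = params.key_bits
    merged = batcher_merge(be_large, s1sub.records, s2sub.records, ell)
    keys, cols = _columns(merged)
    nb = s1sub.n_blocks
    a = be_large.eq_vec(keys[:-1], keys[1:], ell)
    b = _eq_blocks(be_large, [c[:-1] for c in cols[:nb]],
                   [c[1:] for c in cols[:nb]], s1sub.block_bits)
    c = _eq_blocks(be_large, [c[:-1] for c in cols[nb:]],
                   [c[1:] for c in cols[nb:]], s1sub.block_bits)
    t = be_large.sub_vec(b, be_large.mult_vec(b, c))
    u = be_large.mult_vec(a, be_large.affine_vec(t, 1, -1))
    terms = be_large.add_vec(be_large.affine_vec(a, -1, 1), u)
    dist1 = be_large.total(terms)
    dist1 = be_large.add_vec([dist1], [s1sub.d_shared])
    dist1 = be_large.add_vec(dist1, [s2sub.d_shared])
    dist1 = be_large.affine_vec(dist1, 1, -1)[0]

    dist2 = _scan_snpsub_pow2(be_small, s1ss, s2ss, params)
    # dist2 may be transiently negative relative to 0 (offset compensation);
    # shift by a public bound before the cross-modulus conversion
    offset = len(s1ss.records) + len(s2ss.records) + 2
    ell_conv = (2 * offset).bit_length() + 1
    shifted = be_small.affine_vec([dist2], 1, offset)
    conv = be_small.convert_vec(shifted, be_large, ell_conv)
    total = be_large.add_vec([dist1], be_large.affine_vec(conv, 1, -offset))
    return _decode_dist(be_large, total[0])


def secure_hd_newmerge(be: Backend, s1: SharedSet, s2: SharedSet,
                       params: EncodingParams) -> int:
    """Arbitrary-size scheme over the generalised merge.

    Keys are location-transformed (4V1 / 4V1+1) so an equal-key adjacent
    pair can only be a merge duplicate (ignored), a key difference of
    exactly 1 marks a genuine cross-set location match, and dummies
    self-cancel (+1 for the first of site 1, -1 for the first of site 2),
    so no dummy-count correction term is needed.
    """
    ell = params.transformed_key_bits
    merged = new_merge(be, s1.records, s2.records, ell)
    keys, cols = _columns(merged)
    nb = s1.n_blocks
    a = be.eq_vec(keys[:-1], keys[1:], ell)
    dd = be.eq_vec(be.affine_vec(keys[:-1], 1, 1), keys[1:], ell + 1)
    b = _eq_blocks(be, [c[:-1] for c in cols[:nb]], [c[1:] for c in cols[:nb]],
                   s1.block_bits)
    c = _eq_blocks(be, [c[:-1] for c in cols[nb:]], [c[1:] for c in cols[nb:]],
                   s1.block_bits)
    t = be.sub_vec(b, be.mult_vec(b, c))
    m2 = be.mult_vec(dd, t)
    inner = be.add_vec(be.affine_vec(dd, -2, 1), m2)  # 1 - 2d + d*t
    terms = be.mult_vec(be.affine_vec(a, -1, 1), inner)
    dist = be.total(terms)
    dist = be.affine_vec([dist], 1, 1)  # first record
    return _decode_dist(be, dist[0])


def secure_hd_full(be_large: Backend, be_small: Backend,
                   s1sub: SharedSet, s2sub: SharedSet,
                   s1ss: SharedSet, s2ss: SharedSet,
                   params: EncodingParams) -> int:
    """Both optimisations: generalised merge on transformed keys for the SUB
    pass and for the compact SNP&SUB pass, combined across moduli."""
    ell = params.transformed_key_bits
    merged = new_merge(be_large, s1sub.records, s2sub.records, ell)
    keys, cols = _columns(merged)
    nb = s1sub.n_blocks
    a = be_large.eq_vec(keys[:-1], keys[1:], ell)
    dd = be_large.eq_vec(be_large.affine_vec(keys[:-1], 1, 1), keys[1:], ell + 1)
    b = _eq_blocks(be_large, [c[:-1] for c in cols[:nb]],
                   [c[1:] for c in cols[:nb]], s1sub.block_bits)
    c = _eq_blocks(be_large, [c[:-1] for c in cols[nb:]],
                   [c[1:] for c in cols[nb:]], s1sub.block_bits)
    t = be_large.sub_vec(b, be_large.mult_vec(b, c))
    m2 = be_large.mult_vec(dd, t)
    inner = be_large.add_vec(be_large.affine_vec(dd, -2, 1), m2)
    terms = be_large.mult_vec(be_large.affine_vec(a, -1, 1), inner)
    dist1 = be_large.affine_vec([be_large.total(terms)], 1, 1)[0]

    merged2 = new_merge(be_small, s1ss.records, s2ss.records, ell)
    keys2, (v2, v3, v4) = _columns(merged2)
    a2 = be_small.eq_vec(keys2[:-1], keys2[1:], ell)
    g = be_small.eq_vec(be_small.affine_vec(keys2[:-1], 1, 1), keys2[1:], ell + 1)
    b2 = be_small.eq_vec(v2[:-1], v2[1:], 3)
    c2 = be_small.eq_vec(v3[:-1], v3[1:], 3)
    v4p, v4c = v4[:-1], v4[1:]
    d2b, e2 = be_small.or_xor_vec(v4p, v4c)
    t2 = be_small.sub_vec(b2, be_small.mult_vec(b2, c2))
    inner1 = be_small.add_vec(
        v4c, be_small.mult_vec(g, be_small.sub_vec(be_small.sub_vec(t2, v4p), v4c)))
    m2b = be_small.mult_vec(d2b, inner1)
    m3 = be_small.mult_vec(g, e2)
    terms2 = be_small.mult_vec(be_small.affine_vec(a2, -1, 1),
                               be_small.sub_vec(m2b, m3))
    dist2 = be_small.add_vec([be_small.total(terms2)], [v4[0]])[0]

    offset = len(merged2) + 2
    ell_conv = (2 * offset).bit_length() + 1
    shifted = be_small.affine_vec([dist2], 1, offset)
    conv = be_small.convert_vec(shifted, be_large, ell_conv)
    total = be_large.add_vec([dist1], be_large.affine_vec(conv, 1, -offset))
    return _decode_dist(be_large, total[0])


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class HammingRun:
    distance: int
    scheme: str
    backend: str
    set_sizes: dict
    rounds: int
    messages: int


def _contexts(params: EncodingParams, kappa: int, seed: int | None,
              need_small: bool) -> tuple[MpcContext, MpcContext | None]:
    kb = max(params.key_bits, params.transformed_key_bits) + 1
    large_bits = max(HAMMING_LARGE_MODULUS_BITS, kb + kappa + 3)
    ctx_l = MpcContext(smallest_prime_above(large_bits), kappa=kappa, seed=seed)
    ctx_s = None
    if need_small:
        small_bits = max(HAMMING_SMALL_MODULUS_BITS, kb + kappa + 3)
        ctx_s = MpcContext(smallest_prime_above(small_bits), kappa=kappa,
                           seed=None if seed is None else seed + 1)
    return ctx_l, ctx_s


def hamming_distance(records1: Sequence[VariantRecord],
                     records2: Sequence[VariantRecord], *,
                     scheme: str = "full", params: EncodingParams | None = None,
                     backend: str = "secure", kappa: int = 40,
                     seed: int | None = None) -> HammingRun:
    """Run one secure Hamming distance scheme end to end.

    ``records_i`` are the raw datasets; their total sizes N_i are public.
    Filtering, encoding and padding model the input-preparation phase of
    the two data owners; sharing, merging and scanning the execution phase.
    """
    params = params or EncodingParams()
    N1, N2 = len(records1), len(records2)
    need_small = scheme in ("split", "full")
    ctx_l, ctx_s = _contexts(params, kappa, seed, need_small)
    be_l = make_backend(backend, ctx_l)
    be_s = make_backend(backend, ctx_s) if ctx_s else None

    def rel(records):
        return [encode_record(r, "SUB_full", params)
                for r in filter_records(records)]

    def rel_sub(records):
        return [encode_record(r, "SUB_full", params)
                for r in records if r.svtype == "SUB"]

    def rel_compact(records):
        return [encode_record(r, "SNPSUB_compact", params)
                for r in filter_records(records)]

    sizes: dict = {"N1": N1, "N2": N2}
    if scheme == "basic":
        t1, t2, q = padded_sizes_pow2(N1, N2, params.alpha)
        e1 = pad_dummies(rel(records1), t1, "full", params)
        e2 = pad_dummies(rel(records2), t2, "full", params)
        sizes["combined"] = 1 << q
        s1 = share_encoded_set(be_l, e1, params)
        s2 = share_encoded_set(be_l, e2, params)
        dist = secure_hd_basic(be_l, s1, s2, params)
    elif scheme == "split":
        t1, t2, qs = padded_sizes_pow2(N1, N2, params.alpha_s)
        u1, u2, q = padded_sizes_pow2(N1, N2, params.alpha)
        e1sub = pad_dummies(rel_sub(records1), t1, "full", params)
        e2sub = pad_dummies(rel_sub(records2), t2, "full", params)
        e1ss = pad_dummies(rel_compact(records1), u1, "compact", params)
        e2ss = pad_dummies(rel_compact(records2), u2, "compact", params)
        sizes["combined_sub"] = 1 << qs
        sizes["combined_snpsub"] = 1 << q
        dist = secure_hd_split(
            be_l, be_s,
            share_encoded_set(be_l, e1sub, params),
            share_encoded_set(be_l, e2sub, params),
            share_encoded_set(be_s, e1ss, params),
            share_encoded_set(be_s, e2ss, params), params)
    elif scheme == "newmerge":
        t1 = math.floor(params.alpha * N1) + 1
        t2 = math.floor(params.alpha * N2) + 1
        e1 = pad_dummies(rel(records1), t1, "full", params)
        e2 = pad_dummies(rel(records2), t2, "full", params)
        sizes["padded"] = (t1, t2)
        s1 = share_encoded_set(be_l, e1, params, transform_site=1)
        s2 = share_encoded_set(be_l, e2, params, transform_site=2)
        dist = secure_hd_newmerge(be_l, s1, s2, params)
    elif scheme == "full":
        t1 = math.floor(params.alpha_s * N1) + 1
        t2 = math.floor(params.alpha_s * N2) + 1
        u1 = math.floor(params.alpha * N1) + 1
        u2 = math.floor(params.alpha * N2) + 1
        e1sub = pad_dummies(rel_sub(records1), t1, "full", params)
        e2sub = pad_dummies(rel_sub(records2), t2, "full", params)
        e1ss = pad_dummies(rel_compact(records1), u1, "compact", params)
        e2ss = pad_dummies(rel_compact(records2), u2, "compact", params)
        sizes["padded_sub"] = (t1, t2)
        sizes["padded_snpsub"] = (u1, u2)
        dist = secure_hd_full(
            be_l, be_s,
            share_encoded_set(be_l, e1sub, params, transform_site=1),
            share_encoded_set(be_l, e2sub, params, transform_site=2),
            share_encoded_set(be_s, e1ss, params, transform_site=1),
            share_encoded_set(be_s, e2ss, params, transform_site=2), params)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rounds = ctx_l.transcript.rounds + (ctx_s.transcript.rounds if ctx_s else 0)
    msgs = ctx_l.transcript.messages + (ctx_s.transcript.messages if ctx_s else 0)
    return HammingRun(distance=dist, scheme=scheme, backend=backend,
                      set_sizes=sizes, rounds=rounds, messages=msgs)
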