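"""Building-block protocols: oracle equivalence, batching, round accounting."""

import random

import pytest

from genoshare.primitives import (
    ClearBackend,
    SecureBackend,
    div_rounds,
    eq_rounds,
    lt_rounds,
)
from genoshare.sharing import ModulusMismatchError, MpcContext


def test_mult_matches_cleartext_product(secure_be):
    be = secure_be(40, seed=2)
    rng = random.Random(3)
    xs = [rng.randrange(1 << 40) for _ in range(1000)]
    ys = [rng.randrange(1 << 40) for _ in range(1000)]
    got = be.open_vec(be.mult_vec(be.input_vec(xs), be.input_vec(ys)))
    assert got == [(x * y) % be.p for x, y in zip(xs, ys)]


def test_mult_absorbing_and_identity(secure_be):
    be = secure_be(16, seed=4)
    a = be.input_vec([3, 7])
    z = be.input_vec([4, 0])
    assert be.open_vec(be.mult_vec(a, z)) == [12, 0]


def test_mult_mixed_moduli_rejected(secure_be):
    be1 = secure_be(16, seed=5)
    be2 = secure_be(60, seed=5)
    with pytest.raises(ModulusMismatchError):
        be1.mult_vec(be1.input_vec([1]), be2.input_vec([1]))


def test_eq_lt_exhaustive_small_domain(any_be):
    """Brute-force oracle over all 256 pairs in [0,16)^2 at ell=4."""
    be = any_be(8, seed=6)
    pairs = [(x, y) for x in range(16) for y in range(16)]
    xs = be.input_vec([p[0] for p in pairs])
    ys = be.input_vec([p[1] for p in pairs])
    eq = be.open_vec(be.eq_vec(xs, ys, 4))
    lt = be.open_vec(be.lt_vec(xs, ys, 4))
    assert eq == [int(x == y) for x, y in pairs]
    assert lt == [int(x < y) for x, y in pairs]
    assert set(eq) <= {0, 1} and set(lt) <= {0, 1}


@pytest.mark.parametrize("x,y,expect_eq,expect_lt", [
    (5, 5, 1, 0),   # equality, and strictness of LT
    (3, 5, 0, 1),
    (5, 3, 0, 0),
    (0, 0, 1, 0),
])
def test_eq_lt_examples(secure_be, x, y, expect_eq, expect_lt):
    be = secure_be(10, seed=7)
    a, b = be.input_vec([x]), be.input_vec([y])
    assert be.open_vec(be.eq_vec(a, b, 4)) == [expect_eq]
    assert be.open_vec(be.lt_vec(a, b, 4)) == [expect_lt]


def test_eq_lt_wide_operands(secure_be):
    be = secure_be(70, seed=8)
    rng = random.Random(9)
    xs = [rng.randrange(1 << 64) for _ in range(40)]
    ys = [x if i % 3 == 0 else rng.randrange(1 << 64)
          for i, x in enumerate(xs)]
    assert be.open_vec(be.eq_vec(be.input_vec(xs), be.input_vec(ys), 64)) == \
        [int(x == y) for x, y in zip(xs, ys)]
    assert be.open_vec(be.lt_vec(be.input_vec(xs), be.input_vec(ys), 64)) == \
        [int(x < y) for x, y in zip(xs, ys)]


def test_int_div_examples(secure_be):
    be = secure_be(60, seed=10)
    x = be.input_vec([17, (1 << 21) * 144])
    y = be.input_vec([5, 15])
    got = be.open_vec(be.div_vec(x, y, 30))
    assert got == [3, ((1 << 21) * 144) // 15]


def test_int_div_random_oracle_cleartext(clear_be):
    be = clear_be(48, seed=11)
    rng = random.Random(12)
    xs = [rng.randrange(1 << 24) for _ in range(500)]
    ys = [rng.randrange(1, 1 << 24) for _ in range(500)]
    got = be.div_vec(be.input_vec(xs), be.input_vec(ys), 24)
    assert got == [x // y for x, y in zip(xs, ys)]


def test_int_div_random_oracle_secure(secure_be):
    be = secure_be(47, seed=13)
    rng = random.Random(14)
    xs = [rng.randrange(1 << 24) for _ in range(60)]
    ys = [rng.randrange(1, 1 << 24) for _ in range(60)]
    got = be.open_vec(be.div_vec(be.input_vec(xs), be.input_vec(ys), 24))
    assert got == [x // y for x, y in zip(xs, ys)]


def test_float_div_examples(secure_be):
    be = secure_be(40, seed=15)
    d = be.input_vec([144, 9, 15])
    c = be.input_vec([15, 9, 15])
    q, E = be.float_div_vec(d, c, 21, d_bits=8, c_bits=5)
    qv = be.open_vec(q)
    ev = be.open_signed_vec(E)
    vals = [x * 2.0 ** e for x, e in zip(qv, ev)]
    assert vals[1] == pytest.approx(1.0, rel=2 ** -20)  # d = c
    assert vals[2] == pytest.approx(1.0, rel=2 ** -20)
    assert vals[0] == pytest.approx(9.6, rel=2 ** -20)


def test_float_div_random_relative_error(secure_be):
    be = secure_be(40, seed=16)
    rng = random.Random(17)
    prec = 18
    ds = [rng.randrange(0, 1 << 16) for _ in range(30)]
    cs = [rng.randrange(1, 1 << 12) for _ in range(30)]
    q, E = be.float_div_vec(be.input_vec(ds), be.input_vec(cs), prec,
                            d_bits=16, c_bits=12)
    for d, c, qq, ee in zip(ds, cs, be.open_vec(q), be.open_signed_vec(E)):
        exact = d / c
        got = qq * 2.0 ** ee
        if exact == 0:
            assert got == 0
        else:
            assert abs(got - exact) / exact <= 2 ** (1 - prec)


def test_bool_ops_truth_tables(any_be):
    be = any_be(8, seed=18)
    pairs = [(0, 0), (0, 1), (1, 0), (1, 1)]
    x = be.input_vec([p[0] for p in pairs])
    y = be.input_vec([p[1] for p in pairs])
    orr, xorr = be.or_xor_vec(x, y)
    assert be.open_vec(orr) == [0, 1, 1, 1]
    assert be.open_vec(xorr) == [0, 1, 1, 0]


def test_bool_ops_single_multiplication_round(secure_be):
    be = secure_be(8, seed=19)
    x = be.input_vec([1, 0, 1])
    y = be.input_vec([1, 1, 0])
    before = be.ctx.transcript.rounds
    be.or_xor_vec(x, y)
    assert be.ctx.transcript.rounds - before == 1


def test_convert_modulus_preserves_values():
    ctx1 = MpcContext.for_bitlength(60, seed=20)
    ctx2 = MpcContext.for_bitlength(90, seed=21)
    be1, be2 = SecureBackend(ctx1), SecureBackend(ctx2)
    rng = random.Random(22)
    vals = [0, 37] + [rng.randrange(1 << 12) for _ in range(500)]
    conv = be1.convert_vec(be1.input_vec(vals), be2, 13)
    assert be2.open_vec(conv) == vals
    # conversion itself is one round on the source side
    before = ctx1.transcript.rounds
    be1.convert_vec(be1.input_vec([5]), be2, 13)
    assert ctx1.transcript.rounds - before == 1


@pytest.mark.parametrize("op", ["mult", "eq", "lt"])
def test_batching_adds_no_rounds(any_be, op):
    """m parallel invocations cost the same rounds as a single one."""
    def run(be, m):
        xs = be.input_vec(list(range(m)))
        ys = be.input_vec(list(range(m, 2 * m)))
        before = be.ctx.transcript.rounds
        if op == "mult":
            be.mult_vec(xs, ys)
        elif op == "eq":
            be.eq_vec(xs, ys, 8)
        else:
            be.lt_vec(xs, ys, 8)
        return be.ctx.transcript.rounds - before

    assert run(any_be(16, seed=23), 1) == run(any_be(16, seed=23), 64)


def test_secure_round_counts_match_formulas(secure_be):
    for ell in (1, 4, 11, 36):
        be = secure_be(40, seed=24)
        xs, ys = be.input_vec([1, 2]), be.input_vec([3, 2])
        r0 = be.ctx.transcript.rounds
        be.eq_vec(xs, ys, ell)
        assert be.ctx.transcript.rounds - r0 == eq_rounds(ell)
        r0 = be.ctx.transcript.rounds
        be.lt_vec(xs, ys, ell)
        assert be.ctx.transcript.rounds - r0 == lt_rounds(ell)
    be = secure_be(30, seed=25)
    xs, ys = be.input_vec([100]), be.input_vec([7])
    r0 = be.ctx.transcript.rounds
    be.div_vec(xs, ys, 10)
    assert be.ctx.transcript.rounds - r0 == div_rounds(10)


def test_operand_capacity_enforced(secure_be):
    be = secure_be(16, seed=26)  # modulus sized for 16-bit operands only
    xs, ys = be.input_vec([1]), be.input_vec([2])
    with pytest.raises(ValueError, match="too small"):
        be.lt_vec(xs, ys, 120)
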