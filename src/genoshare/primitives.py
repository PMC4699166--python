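"""Interactive building blocks on secret-shared integers.

Two interchangeable backends expose the same vectorised protocol surface:

* :class:`SecureBackend` runs genuine three-party protocols on Shamir shares
  (simulated synchronously in-process).  Multiplication is the classic
  degree-reduction protocol: parties multiply their shares locally (degree-2
  points) and re-share, taking a public Lagrange recombination — one round.
  Equality, comparison and division are realised with statistically masked
  openings: a dealer-style preprocessing phase supplies shared random bits,
  a masked value is opened publicly (statistical hiding parameter ``kappa``),
  and the result is assembled from local affine steps plus logarithmic-depth
  trees of batched multiplications.
* :class:`ClearBackend` evaluates the same operations directly on plain
  integers while charging the identical round structure to its transcript.
  It is the oracle twin: every protocol in this package runs unchanged over
  either backend, and tests assert that reconstructed secure results equal
  the cleartext ones.

All vector operations are *batched*: ``m`` independent invocations cost the
same number of rounds as one, which is what makes single-batch execution of
a whole SNP panel (or one merge stride) possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .sharing import (
    IntegrityError,
    ModulusMismatchError,
    MpcContext,
    ShareVector,
)

__all__ = [
    "BitlengthParams",
    "SecureBackend",
    "ClearBackend",
    "eq_rounds",
    "lt_rounds",
    "div_rounds",
    "float_div_rounds",
]


@dataclass(frozen=True)
class BitlengthParams:
    """Public bitlength bounds of protocol operands.

    ``ell`` bounds comparison operands, ``f`` bounds division operands and
    ``k_bits`` is the precision scale factor (in bits) applied before integer
    division.  The sharing modulus must satisfy ``2**(ell+kappa+1) < p`` for
    every protocol that uses statistical masking.
    """

    ell: int
    f: int = 0
    k_bits: int = 21


def _ceil_log2(x: int) -> int:
    if x <= 1:
        return 0
    return (x - 1).bit_length()


# ---------------------------------------------------------------------------
# Round-cost formulas (shared by both backends; the secure backend's actual
# transcript is asserted against these in the test suite).

def eq_rounds(ell: int) -> int:
    return 1 + _ceil_log2(ell)


def lt_rounds(ell: int) -> int:
    return 1 + _ceil_log2(ell)


def div_rounds(f: int, y_bits: int | None = None, q_bits: int | None = None) -> int:
    y_bits = y_bits if y_bits is not None else f
    q_bits = q_bits if q_bits is not None else f
    return sum(lt_rounds(max(f, y_bits + j)) + 1 for j in range(q_bits))


def bitdec_rounds(ell: int) -> int:
    return 2 + _ceil_log2(ell + 1)


def normalize_rounds(ell: int) -> int:
    return bitdec_rounds(ell) + _ceil_log2(ell) + 1


def float_div_rounds(prec: int, d_bits: int, c_bits: int) -> int:
    s = prec + 1 + max(0, c_bits - d_bits)
    q_bits = d_bits + s - (c_bits - 1)
    return (normalize_rounds(d_bits) + normalize_rounds(c_bits)
            + div_rounds(d_bits + s, y_bits=c_bits, q_bits=q_bits))


# ---------------------------------------------------------------------------
# Secure backend

# internal batched representation: one list of shares per party
_RVec = tuple[list[int], list[int], list[int]]


class SecureBackend:
    """Protocol suite over Shamir shares; handles are :class:`ShareVector`."""

    name = "secure"

    def __init__(self, ctx: MpcContext):
        self.ctx = ctx
        self.p = ctx.p
        self.kappa = ctx.kappa

    # -- handle plumbing ----------------------------------------------------

    def _unwrap(self, svs: Sequence[ShareVector]) -> _RVec:
        p = self.p
        a, b, c = [], [], []
        for sv in svs:
            if sv.p != p:
                raise ModulusMismatchError("share under a different modulus")
            s = sv.shares
            a.append(s[0]); b.append(s[1]); c.append(s[2])
        return a, b, c

    def _wrap(self, rv: _RVec) -> list[ShareVector]:
        p = self.p
        return [ShareVector((x, y, z), p) for x, y, z in zip(*rv)]

    # -- local (non-interactive) arithmetic --------------------------------

    def _share_one(self, x: int, rng) -> tuple[int, int, int]:
        p = self.p
        c = rng.randrange(p)
        return ((x + c) % p, (x + 2 * c) % p, (x + 3 * c) % p)

    def _input_rv(self, values: Sequence[int], rng=None) -> _RVec:
        rng = rng or self.ctx.input_rng
        p = self.p
        out: _RVec = ([], [], [])
        for v in values:
            s = self._share_one(v % p, rng)
            out[0].append(s[0]); out[1].append(s[1]); out[2].append(s[2])
        return out

    def input_vec(self, values: Sequence[int]) -> list[ShareVector]:
        return self._wrap(self._input_rv(values))

    def const_vec(self, values: Sequence[int]) -> list[ShareVector]:
        """Public constants as (degenerate, constant-polynomial) sharings."""
        p = self.p
        return [ShareVector((v % p, v % p, v % p), p) for v in values]

    def _const_rv(self, values: Sequence[int]) -> _RVec:
        p = self.p
        vs = [v % p for v in values]
        return (list(vs), list(vs), list(vs))

    @staticmethod
    def _add_rv(a: _RVec, b: _RVec, p: int) -> _RVec:
        return tuple([(x + y) % p for x, y in zip(a[i], b[i])] for i in range(3))  # type: ignore

    @staticmethod
    def _sub_rv(a: _RVec, b: _RVec, p: int) -> _RVec:
        return tuple([(x - y) % p for x, y in zip(a[i], b[i])] for i in range(3))  # type: ignore

    @staticmethod
    def _affine_rv(a: _RVec, mul, add, p: int) -> _RVec:
        """``mul*x + add`` with public per-element (or scalar) coefficients."""
        n = len(a[0])
        mv = mul if isinstance(mul, list) else [mul] * n
        av = add if isinstance(add, list) else [add] * n
        return tuple([(m * x + ad) % p for m, x, ad in zip(mv, a[i], av)]
                     for i in range(3))  # type: ignore

    def add_vec(self, a, b):
        return self._wrap(self._add_rv(self._unwrap(a), self._unwrap(b), self.p))

    def sub_vec(self, a, b):
        return self._wrap(self._sub_rv(self._unwrap(a), self._unwrap(b), self.p))

    def affine_vec(self, a, mul=1, add=0):
        return self._wrap(self._affine_rv(self._unwrap(a), mul, add, self.p))

    def sum_vec(self, columns: Sequence[Sequence[ShareVector]]) -> list[ShareVector]:
        """Element-wise sum of several equally long columns (local)."""
        p = self.p
        acc = self._unwrap(columns[0])
        for col in columns[1:]:
            acc = self._add_rv(acc, self._unwrap(col), p)
        return self._wrap(acc)

    def total(self, col: Sequence[ShareVector]) -> ShareVector:
        """Sum of all entries of one column (local)."""
        p = self.p
        rv = self._unwrap(col)
        return ShareVector(tuple(sum(rv[i]) % p for i in range(3)), p)  # type: ignore

    # -- interactive core ---------------------------------------------------

    def _charge(self, kind: str, n: int) -> None:
        # one synchronous all-to-all exchange: each party sends to the other 2
        self.ctx.transcript.record_round(kind, 6, n)

    def _open_rv(self, rv: _RVec, kind: str = "open") -> list[int]:
        p = self.p
        self._charge(kind, len(rv[0]))
        out = []
        for s1, s2, s3 in zip(*rv):
            if s3 != (2 * s2 - s1) % p:
                raise IntegrityError("inconsistent shares at opening")
            out.append((2 * s1 - s2) % p)
        return out

    def _mult_rv(self, a: _RVec, b: _RVec, kind: str = "mult") -> _RVec:
        """Degree-reduction multiplication; one round for the whole batch."""
        p = self.p
        n = len(a[0])
        self._charge(kind, n)
        new1 = [0] * n
        new2 = [0] * n
        new3 = [0] * n
        lam = (3, p - 3, 1)  # Lagrange coefficients at 0 for points 1,2,3
        rngs = self.ctx.party_rng
        for i in range(3):
            li = lam[i]
            ai, bi = a[i], b[i]
            rng = rngs[i]
            for k in range(n):
                d = ai[k] * bi[k] % p
                c = rng.randrange(p)
                new1[k] += li * (d + c)
                new2[k] += li * (d + 2 * c)
                new3[k] += li * (d + 3 * c)
        return ([x % p for x in new1], [x % p for x in new2], [x % p for x in new3])

    def _mult_layers(self, pairs: list[tuple[_RVec, _RVec]],
                     kind: str = "mult") -> list[_RVec]:
        """Multiply several independent layer pairs in a single round."""
        xs: _RVec = ([], [], [])
        ys: _RVec = ([], [], [])
        sizes = []
        for a, b in pairs:
            sizes.append(len(a[0]))
            for i in range(3):
                xs[i].extend(a[i]); ys[i].extend(b[i])
        prod = self._mult_rv(xs, ys, kind)
        out = []
        pos = 0
        for sz in sizes:
            out.append(tuple(prod[i][pos:pos + sz] for i in range(3)))
            pos += sz
        return out  # type: ignore

    # -- preprocessing (dealer) randomness ----------------------------------

    def _rand_bits(self, n: int) -> _RVec:
        rng = self.ctx.dealer_rng
        return self._input_rv([rng.getrandbits(1) for _ in range(n)], rng)

    def _rand_field(self, n: int, bound: int) -> _RVec:
        rng = self.ctx.dealer_rng
        return self._input_rv([rng.randrange(bound) for _ in range(n)], rng)

    # -- protocol helpers ---------------------------------------------------

    def _check_capacity(self, ell: int) -> None:
        if ell + self.kappa + 3 > self.p.bit_length():
            raise ValueError(
                f"modulus of {self.p.bit_length()} bits too small for "
                f"{ell}-bit operands at kappa={self.kappa}")

    def _prod_tree(self, layers: list[_RVec], kind: str) -> _RVec:
        """Batched product of bit layers; ceil(log2(len)) rounds."""
        while len(layers) > 1:
            pairs = []
            rest = []
            for i in range(0, len(layers) - 1, 2):
                pairs.append((layers[i], layers[i + 1]))
            if len(layers) % 2:
                rest = [layers[-1]]
            layers = self._mult_layers(pairs, kind) + rest
        return layers[0]

    def _suffix_or(self, layers: list[_RVec], kind: str) -> list[_RVec]:
        """``out[i] = OR(layers[i..top])``; ceil(log2(len)) rounds.

        OR(a,b) = a + b - ab, so each level is one batched multiplication.
        """
        p = self.p
        ell = len(layers)
        arr = list(layers)
        s = 1
        while s < ell:
            pairs = [(arr[i], arr[i + s]) for i in range(ell - s)]
            prods = self._mult_layers(pairs, kind)
            new = list(arr)
            for i in range(ell - s):
                ab = prods[i]
                new[i] = tuple(
                    [(x + y - z) % p for x, y, z in zip(arr[i][j], arr[i + s][j], ab[j])]
                    for j in range(3))  # type: ignore
            arr = new
            s *= 2
        return arr

    def _eq_rv(self, x: _RVec, y: _RVec, ell: int) -> _RVec:
        """Shared equality bit via a masked opening and a product tree.

        With z = x - y (|z| < 2**ell) and mask r = r_low + 2**ell * r_hi, the
        public value c = z + r satisfies c = r mod 2**ell iff z = 0, so the
        bit is the AND over bitwise agreements of c and r_low.  Errs with
        probability <= 2**-kappa (mask smaller than |z| wraps mod p).
        """
        self._check_capacity(ell)
        p = self.p
        n = len(x[0])
        rbits = [self._rand_bits(n) for _ in range(ell)]
        rhi = self._rand_field(n, 1 << self.kappa)
        mask = self._affine_rv(rhi, 1 << ell, 0, p)
        for i, rb in enumerate(rbits):
            mask = self._add_rv(mask, self._affine_rv(rb, 1 << i, 0, p), p)
        c = self._open_rv(self._add_rv(self._sub_rv(x, y, p), mask, p), "eq.open")
        # s_i = 1 iff bit i of c equals r_i:  s_i = 1 - c_i - r_i + 2 c_i r_i
        layers = []
        for i, rb in enumerate(rbits):
            cb = [(cv >> i) & 1 for cv in c]
            mul = [2 * b - 1 for b in cb]
            add = [1 - b for b in cb]
            layers.append(self._affine_rv(rb, mul, add, p))
        return self._prod_tree(layers, "eq.and")

    def _bitlt_pub(self, cpub: list[int], rbits: list[_RVec]) -> _RVec:
        """Shared bit ``[c < r]`` for public c and bitwise-shared r (local+OR).

        d_i = c_i XOR r_i; at the most significant differing position,
        r_i = 1 - c_i, so the result is a public-coefficient combination of
        the suffix-OR differences.
        """
        p = self.p
        ell = len(rbits)
        dbits = []
        for i, rb in enumerate(rbits):
            cb = [(cv >> i) & 1 for cv in cpub]
            dbits.append(self._affine_rv(rb, [1 - 2 * b for b in cb], cb, p))
        f = self._suffix_or(dbits, "lt.prefix")
        n = len(cpub)
        acc: _RVec = ([0] * n, [0] * n, [0] * n)
        zero: _RVec = ([0] * n, [0] * n, [0] * n)
        for i in range(ell):
            fi = f[i]
            fnext = f[i + 1] if i + 1 < ell else zero
            e = self._sub_rv(fi, fnext, p)
            coeff = [1 - ((cv >> i) & 1) for cv in cpub]
            acc = self._add_rv(acc, self._affine_rv(e, coeff, 0, p), p)
        return acc

    def _lt_rv(self, x: _RVec, y: _RVec, ell: int) -> _RVec:
        """Shared strict comparison bit via the sign of z = x - y + 2**ell.

        Bit ``ell`` of z (0 < z < 2**(ell+1)) is 1 iff x >= y; it is isolated
        by a masked modulo-2**ell reduction of z.
        """
        self._check_capacity(ell)
        p = self.p
        n = len(x[0])
        z = self._affine_rv(self._sub_rv(x, y, p), 1, 1 << ell, p)
        rbits = [self._rand_bits(n) for _ in range(ell)]
        rhi = self._rand_field(n, 1 << (self.kappa + 1))
        mask = self._affine_rv(rhi, 1 << ell, 0, p)
        for i, rb in enumerate(rbits):
            mask = self._add_rv(mask, self._affine_rv(rb, 1 << i, 0, p), p)
        c = self._open_rv(self._add_rv(z, mask, p), "lt.open")
        cp = [cv % (1 << ell) for cv in c]
        u = self._bitlt_pub(cp, rbits)  # borrow bit: 1 iff cp < r_low
        # z mod 2**ell = cp - r_low + 2**ell * u
        low: _RVec = self._affine_rv(u, 1 << ell, cp, p)
        for i, rb in enumerate(rbits):
            low = self._sub_rv(low, self._affine_rv(rb, 1 << i, 0, p), p)
        inv = pow(1 << ell, -1, p)
        h = self._affine_rv(self._sub_rv(z, low, p), inv, 0, p)
        return self._affine_rv(h, p - 1, 1, p)  # 1 - h

    # -- public vector protocols -------------------------------------------

    def open_vec(self, svs: Sequence[ShareVector]) -> list[int]:
        return self._open_rv(self._unwrap(svs))

    def open_signed_vec(self, svs: Sequence[ShareVector]) -> list[int]:
        p = self.p
        return [v - p if v > p // 2 else v for v in self.open_vec(svs)]

    def mult_vec(self, a, b) -> list[ShareVector]:
        return self._wrap(self._mult_rv(self._unwrap(a), self._unwrap(b)))

    def eq_vec(self, a, b, ell: int) -> list[ShareVector]:
        return self._wrap(self._eq_rv(self._unwrap(a), self._unwrap(b), ell))

    def lt_vec(self, a, b, ell: int) -> list[ShareVector]:
        return self._wrap(self._lt_rv(self._unwrap(a), self._unwrap(b), ell))

    def or_xor_vec(self, x, y) -> tuple[list[ShareVector], list[ShareVector]]:
        """(OR, XOR) of shared bits from a single shared multiplication."""
        p = self.p
        xr, yr = self._unwrap(x), self._unwrap(y)
        m = self._mult_rv(xr, yr, "bool.mult")
        s = self._add_rv(xr, yr, p)
        orr = self._sub_rv(s, m, p)
        xorr = self._sub_rv(orr, m, p)
        return self._wrap(orr), self._wrap(xorr)

    def div_vec(self, x, y, f: int, *, y_bits: int | None = None,
                q_bits: int | None = None) -> list[ShareVector]:
        """Exact floor division by oblivious restoring long division.

        Caller guarantees 0 <= x < 2**f and 0 < y < 2**y_bits; with the
        default q_bits = f the quotient bound holds for any such inputs.
        """
        p = self.p
        y_bits = y_bits if y_bits is not None else f
        q_bits = q_bits if q_bits is not None else f
        R = self._unwrap(x)
        Y = self._unwrap(y)
        n = len(R[0])
        Q: _RVec = ([0] * n, [0] * n, [0] * n)
        for j in reversed(range(q_bits)):
            ys = self._affine_rv(Y, 1 << j, 0, p)
            ell = max(f, y_bits + j)
            lt = self._lt_rv(R, ys, ell)
            ge = self._affine_rv(lt, p - 1, 1, p)
            R = self._sub_rv(R, self._mult_rv(ge, ys, "div.mult"), p)
            Q = self._add_rv(Q, self._affine_rv(ge, 1 << j, 0, p), p)
        return self._wrap(Q)

    def _bitdec_rv(self, a: _RVec, ell: int) -> list[_RVec]:
        """Shared bits of a (0 <= a < 2**ell) via a masked opening and a
        carry-lookahead subtraction circuit on public/shared bit vectors."""
        self._check_capacity(ell)
        p = self.p
        n = len(a[0])
        rbits = [self._rand_bits(n) for _ in range(ell)]
        rhi = self._rand_field(n, 1 << self.kappa)
        mask = self._affine_rv(rhi, 1 << ell, 0, p)
        for i, rb in enumerate(rbits):
            mask = self._add_rv(mask, self._affine_rv(rb, 1 << i, 0, p), p)
        c = self._open_rv(self._add_rv(a, mask, p), "bitdec.open")
        # a = (c - r) mod 2**ell = c + ~r + 1 mod 2**ell (two's complement)
        gp: list[tuple[_RVec, _RVec]] = []
        # virtual carry-in element: (g, p) = (1, 0)
        one: _RVec = ([1] * n, [1] * n, [1] * n)
        zero: _RVec = ([0] * n, [0] * n, [0] * n)
        gp.append((one, zero))
        pvec: list[_RVec] = []
        for i, rb in enumerate(rbits):
            cb = [(cv >> i) & 1 for cv in c]
            nb = self._affine_rv(rb, p - 1, 1, p)  # ~r_i
            g = self._affine_rv(nb, cb, 0, p)      # c_i AND ~r_i (public c_i)
            pr = self._affine_rv(nb, [1 - 2 * b for b in cb], cb, p)  # XOR
            gp.append((g, pr))
            pvec.append(pr)
        # Hillis-Steele prefix of the carry operator (g2,p2)o(g1,p1)
        m = len(gp)
        s = 1
        while s < m:
            pairs = []
            idx = []
            for i in range(s, m):
                g1, p1 = gp[i - s]
                g2, p2 = gp[i]
                pairs.append((p2, g1))
                pairs.append((p2, p1))
                idx.append(i)
            prods = self._mult_layers(pairs, "bitdec.prefix")
            new = list(gp)
            for k, i in enumerate(idx):
                pg = prods[2 * k]
                pp = prods[2 * k + 1]
                g2 = gp[i][0]
                new[i] = (self._add_rv(g2, pg, p), pp)
            gp = new
            s *= 2
        # sum bit i = p_i XOR carry_in(i); carry_in(i) = G(prefix through i)
        pairs = [(pvec[i], gp[i][0]) for i in range(ell)]
        prods = self._mult_layers(pairs, "bitdec.sum")
        bits = []
        for i in range(ell):
            ki = gp[i][0]
            t = self._add_rv(pvec[i], ki, p)
            bits.append(self._sub_rv(t, self._affine_rv(prods[i], 2, 0, p), p))
        return bits

    def _normalize_rv(self, a: _RVec, ell: int) -> tuple[_RVec, _RVec]:
        """(significand, exponent) with sig = a * 2**(ell-1-e) in
        [2**(ell-1), 2**ell) for a > 0 (sig = 0 when a = 0)."""
        p = self.p
        n = len(a[0])
        bits = self._bitdec_rv(a, ell)
        f = self._suffix_or(bits, "norm.prefix")
        zero: _RVec = ([0] * n, [0] * n, [0] * n)
        u: _RVec = ([0] * n, [0] * n, [0] * n)
        e: _RVec = ([0] * n, [0] * n, [0] * n)
        for i in range(ell):
            fi = f[i]
            fnext = f[i + 1] if i + 1 < ell else zero
            mi = self._sub_rv(fi, fnext, p)
            u = self._add_rv(u, self._affine_rv(mi, 1 << (ell - 1 - i), 0, p), p)
            e = self._add_rv(e, self._affine_rv(mi, i, 0, p), p)
        sig = self._mult_rv(a, u, "norm.mult")
        return sig, e

    def float_div_vec(self, d, c, precision_bits: int, *, d_bits: int,
                      c_bits: int) -> tuple[list[ShareVector], list[ShareVector]]:
        """Normalised floating-point division with relative error
        <= 2**(1 - precision_bits).

        Returns shared (significand q, exponent E) with d/c ~= q * 2**E;
        exponents may be negative (decode with :meth:`open_signed_vec`).
        Operands are assumed non-negative with c > 0, which lets the
        normalisation skip sign handling.
        """
        p = self.p
        sig_d, e_d = self._normalize_rv(self._unwrap(d), d_bits)
        sig_c, e_c = self._normalize_rv(self._unwrap(c), c_bits)
        s = precision_bits + 1 + max(0, c_bits - d_bits)
        x = self._wrap(self._affine_rv(sig_d, 1 << s, 0, p))
        q = self.div_vec(x, self._wrap(sig_c), d_bits + s, y_bits=c_bits,
                         q_bits=d_bits + s - (c_bits - 1))
        E = self._affine_rv(self._sub_rv(e_d, e_c, p), 1,
                            (- s - d_bits + c_bits) % p, p)
        return q, self._wrap(E)

    def convert_vec(self, xs: Sequence[ShareVector], target: "SecureBackend",
                    ell: int) -> list[ShareVector]:
        """Re-share values (< 2**ell) under the target backend's modulus.

        A dealer-correlated mask r < 2**(ell+kappa), shared under both
        moduli, hides the opened value; one round.
        """
        self._check_capacity(ell)
        target._check_capacity(ell)
        rng = self.ctx.dealer_rng
        rvals = [rng.randrange(1 << (ell + self.kappa)) for _ in range(len(xs))]
        r_here = self._input_rv(rvals, rng)
        r_there = target._input_rv(rvals, rng)
        c = self._open_rv(self._add_rv(self._unwrap(xs), r_here, self.p), "convert.open")
        return target._wrap(target._affine_rv(r_there, target.p - 1, c, target.p))


# ---------------------------------------------------------------------------
# Cleartext backend


class ClearBackend:
    """Plain-integer twin of :class:`SecureBackend`.

    Handles are Python ints; every operation charges the same round structure
    to its transcript so batching claims can be asserted on either backend.
    """

    name = "cleartext"

    def __init__(self, ctx: MpcContext):
        self.ctx = ctx
        self.p = ctx.p
        self.kappa = ctx.kappa

    def _charge(self, kind: str, n: int, rounds: int = 1) -> None:
        for _ in range(rounds):
            self.ctx.transcript.record_round(kind, 6, n)

    def input_vec(self, values):
        return list(values)

    def const_vec(self, values):
        return list(values)

    def open_vec(self, vs):
        self._charge("open", len(vs))
        return list(vs)

    def open_signed_vec(self, vs):
        return self.open_vec(vs)

    def add_vec(self, a, b):
        return [x + y for x, y in zip(a, b)]

    def sub_vec(self, a, b):
        return [x - y for x, y in zip(a, b)]

    def affine_vec(self, a, mul=1, add=0):
        n = len(a)
        mv = mul if isinstance(mul, list) else [mul] * n
        av = add if isinstance(add, list) else [add] * n
        return [m * x + ad for m, x, ad in zip(mv, a, av)]

    def sum_vec(self, columns):
        return [sum(vs) for vs in zip(*columns)]

    def total(self, col):
        return sum(col)

    def mult_vec(self, a, b):
        self._charge("mult", len(a))
        return [x * y for x, y in zip(a, b)]

    def eq_vec(self, a, b, ell):
        self._charge("eq", len(a), eq_rounds(ell))
        return [int(x == y) for x, y in zip(a, b)]

    def lt_vec(self, a, b, ell):
        self._charge("lt", len(a), lt_rounds(ell))
        return [int(x < y) for x, y in zip(a, b)]

    def or_xor_vec(self, x, y):
        self._charge("bool", len(x))
        return ([a | b for a, b in zip(x, y)], [a ^ b for a, b in zip(x, y)])

    def div_vec(self, x, y, f, *, y_bits=None, q_bits=None):
        self._charge("div", len(x), div_rounds(f, y_bits, q_bits))
        return [a // b for a, b in zip(x, y)]

    def float_div_vec(self, d, c, precision_bits, *, d_bits, c_bits):
        self._charge("float_div", len(d),
                     float_div_rounds(precision_bits, d_bits, c_bits))
        s = precision_bits + 1 + max(0, c_bits - d_bits)
        qs, Es = [], []
        for dv, cv in zip(d, c):
            e_d = dv.bit_length() - 1 if dv > 0 else 0
            e_c = cv.bit_length() - 1
            sig_d = dv << (d_bits - 1 - e_d)
            sig_c = cv << (c_bits - 1 - e_c)
            qs.append((sig_d << s) // sig_c)
            Es.append(e_d - e_c - s - d_bits + c_bits)
        return qs, Es

    def convert_vec(self, xs, target, ell):
        self._charge("convert", len(xs))
        return list(xs)


Backend = SecureBackend | ClearBackend


def make_backend(kind: str, ctx: MpcContext) -> Backend:
    if kind == "secure":
        return SecureBackend(ctx)
    if kind == "cleartext":
        return ClearBackend(ctx)
    raise ValueError(f"unknown backend {kind!r}")
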