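"""Prime-field arithmetic and (3,1)-threshold Shamir secret sharing.

A private integer ``x`` in ``[0, p)`` is split into three shares by sampling
a uniformly random degree-1 polynomial ``f`` over ``GF(p)`` with ``f(0) = x``
and handing party ``i`` the evaluation ``f(i)`` (evaluation points are fixed
at ``x = 1, 2, 3``).  Any single share is marginally uniform on ``[0, p)``
and therefore reveals nothing; any two shares determine the secret by
Lagrange interpolation at 0.  Three computational parties with threshold
``t = 1`` satisfy ``t < n/2``, which is what the multiplication protocol in
:mod:`genoshare.primitives` requires.

Linear operations on shared values (addition, subtraction, multiplication by
public constants) are local: each party applies them to its own share, so no
messages are exchanged and the round transcript is untouched.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import sympy


class ShareError(Exception):
    """Base class for secret-sharing errors."""


class RangeError(ShareError):
    """Secret outside the field range ``[0, p)``."""


class ModulusMismatchError(ShareError):
    """Operands shared under different prime moduli were combined."""


class IntegrityError(ShareError):
    """The three shares do not lie on a single degree-<=1 polynomial."""


# Default modulus bitlengths.  Two sharing instances are first-class for the
# Hamming task (a wide one for full REF/ALT string encodings and a narrow one
# for the compact SNP&SUB encoding); the GWAS default matches the bitlength
# used for the MAF / floating-point chi-squared configuration.
GWAS_MODULUS_BITS = 84
HAMMING_LARGE_MODULUS_BITS = 118
HAMMING_SMALL_MODULUS_BITS = 85

_prime_cache: dict[int, int] = {}


def smallest_prime_above(bits: int) -> int:
    """Smallest prime exceeding ``2**bits`` (cached)."""
    if bits not in _prime_cache:
        _prime_cache[bits] = int(sympy.nextprime(1 << bits))
    return _prime_cache[bits]


@dataclass
class Transcript:
    """Ordered record of the synchronous communication of one protocol run.

    One *round* is one all-to-all message exchange.  ``log`` keeps
    ``(round_index, kind, n_messages, payload_elements)`` tuples so tests can
    assert round-count claims (e.g. that batching does not add rounds).
    """

    rounds: int = 0
    messages: int = 0
    elements: int = 0
    log: list[tuple[int, str, int, int]] = field(default_factory=list)

    def record_round(self, kind: str, n_messages: int, payload: int) -> None:
        self.rounds += 1
        self.messages += n_messages
        self.elements += payload
        self.log.append((self.rounds, kind, n_messages, payload))

    def export(self) -> str:
        lines = [f"round\tkind\tmessages\telements"]
        for r, kind, m, e in self.log:
            lines.append(f"{r}\t{kind}\t{m}\t{e}")
        return "\n".join(lines)


class MpcContext:
    """Parameters and state of one simulated three-party computation.

    Parameters
    ----------
    p:
        Prime modulus of the sharing field.  Must satisfy
        ``p > 2**(ell_max + kappa + 1)`` for the largest operand bitlength
        ``ell_max`` used under this modulus with statistical masking.
    kappa:
        Statistical security parameter in bits (default 40): masked openings
        leak at most ``2**-kappa`` statistical distance and the comparison
        protocols err with probability at most ``2**-kappa`` per invocation.
    seed:
        Seeds the per-party pseudorandom generators and the preprocessing
        (dealer) generator.  ``None`` draws a fresh nondeterministic seed.

    The three parties are simulated in one process under a synchronous round
    scheduler; the :class:`Transcript` accounts for every interactive round.
    """

    n_parties = 3
    threshold = 1

    def __init__(self, p: int, *, kappa: int = 40, seed: int | None = None):
        if p <= 3:
            raise ValueError("modulus too small")
        self.p = p
        self.kappa = kappa
        if seed is None:
            seed = random.SystemRandom().getrandbits(63)
        self.seed = seed
        master = random.Random(seed)
        # independent streams: one per party, one for input sharing, one dealer
        self.party_rng = [random.Random(master.getrandbits(64)) for _ in range(3)]
        self.input_rng = random.Random(master.getrandbits(64))
        self.dealer_rng = random.Random(master.getrandbits(64))
        self.transcript = Transcript()

    @classmethod
    def for_bitlength(cls, ell_max: int, *, kappa: int = 40,
                      seed: int | None = None) -> "MpcContext":
        """Context whose modulus supports ``ell_max``-bit operands.

        Chooses the smallest default prime satisfying the masking invariant
        ``p > 2**(ell_max + kappa + 2)``.
        """
        return cls(smallest_prime_above(ell_max + kappa + 2), kappa=kappa, seed=seed)

    def max_operand_bits(self) -> int:
        """Largest operand bitlength safe for masked protocols under ``p``."""
        return self.p.bit_length() - self.kappa - 3


@dataclass(frozen=True, slots=True)
class ShareVector:
    """The three field-element shares of one secret (parties at x=1,2,3)."""

    shares: tuple[int, int, int]
    p: int

    def __post_init__(self):
        if any(not (0 <= s < self.p) for s in self.shares):
            raise RangeError("share outside field range")


def share(x: int, ctx: MpcContext) -> ShareVector:
    """Shamir-share ``x`` with a uniformly random degree-1 polynomial.

    Raises :class:`RangeError` unless ``0 <= x < p``.
    """
    p = ctx.p
    if not (0 <= x < p):
        raise RangeError(f"secret {x} outside [0, {p})")
    c = ctx.input_rng.randrange(p)
    return ShareVector(((x + c) % p, (x + 2 * c) % p, (x + 3 * c) % p), p)


def reconstruct(sv: ShareVector) -> int:
    """Interpolate the sharing polynomial at 0.

    With three points and threshold 1 the degree-1 consistency of the shares
    is checkable; inconsistent shares raise :class:`IntegrityError`.
    """
    s1, s2, s3 = sv.shares
    p = sv.p
    if s3 != (2 * s2 - s1) % p:
        raise IntegrityError("shares do not lie on a degree-1 polynomial")
    return (2 * s1 - s2) % p


def reconstruct_pair(sv: ShareVector, i: int, j: int) -> int:
    """Reconstruct from the two shares of parties ``i`` and ``j`` (1-based).

    Any two of the three shares suffice at threshold 1.
    """
    if i == j or not (1 <= i <= 3 and 1 <= j <= 3):
        raise ValueError("need two distinct parties in 1..3")
    p = sv.p
    si, sj = sv.shares[i - 1], sv.shares[j - 1]
    # Lagrange at 0 for points {i, j}: li = j/(j-i), lj = i/(i-j)
    li = (j * pow(j - i, -1, p)) % p
    lj = (i * pow(i - j, -1, p)) % p
    return (li * si + lj * sj) % p


def lincomb(coeffs: Sequence[int], svs: Sequence[ShareVector],
            const: int = 0) -> ShareVector:
    """Public linear combination ``sum(c_i * secret_i) + const`` on shares.

    Entirely local: adds zero rounds and zero messages to any transcript.
    """
    if len(coeffs) != len(svs):
        raise ValueError("coeffs and shares differ in length")
    if not svs:
        raise ValueError("need at least one shared operand")
    p = svs[0].p
    acc = [const % p, const % p, const % p]
    for c, sv in zip(coeffs, svs):
        if sv.p != p:
            raise ModulusMismatchError("operands under different moduli")
        c %= p
        for k in range(3):
            acc[k] = (acc[k] + c * sv.shares[k]) % p
    return ShareVector((acc[0], acc[1], acc[2]), p)


def share_all(values: Iterable[int], ctx: MpcContext) -> list[ShareVector]:
    return [share(v, ctx) for v in values]
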