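"""Three-phase secure computation of GWAS statistics.

Two input sites hold horizontally partitioned genotypes for a case and a
control group over P SNPs.  Per SNP and site, allele counts are computed
locally (input preparation), secret-shared, aggregated and reduced on shares
(computation execution), and the public scaling is applied only after
reconstruction (output reconstruction) so that shared values stay small.

Statistics, with n_A = 2 n_AA + n_AB and n_B = 2 n_BB + n_AB summed over
both groups and both sites, N' = 2N, N'_c = 2 N_c, N'_t = 2 N_t:

* minor allele frequency       MAF = min(n_A, n_B) / N'
* allele-count chi-squared     X^2 = (n_cA n_tB - n_cB n_tA)^2 N'
                                     / (N'_c N'_t (n_cA+n_tA)(n_cB+n_tB))

On shares, the minimum is one comparison and one multiplication
(res1 = LT(nA,nB)*(nA-nB) + nB) and the chi-squared reduces to three
independent products, one square and one division of k-scaled integers
(res2 = floor(k*d/c)); all interactive steps for all P SNPs run in single
batches, so the round count is independent of P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from .primitives import ClearBackend, SecureBackend, make_backend
from .sharing import MpcContext

GENOTYPES = ("AA", "AB", "BB")


@dataclass
class SiteCounts:
    """Per-SNP allele counts of one input site (alleles, not genotypes:
    homozygotes contribute 2)."""

    ncA: list[int]
    ncB: list[int]
    ntA: list[int]
    ntB: list[int]
    Nc: int
    Nt: int

    def __post_init__(self):
        P = len(self.ncA)
        if not (len(self.ncB) == len(self.ntA) == len(self.ntB) == P):
            raise ValueError("count vectors differ in length")
        for j in range(P):
            if self.ncA[j] + self.ncB[j] != 2 * self.Nc:
                raise ValueError(f"case counts at SNP {j} do not sum to 2*Nc")
            if self.ntA[j] + self.ntB[j] != 2 * self.Nt:
                raise ValueError(f"control counts at SNP {j} do not sum to 2*Nt")

    @property
    def n_snps(self) -> int:
        return len(self.ncA)


def _count_group(rows: Sequence[Sequence[str]]) -> tuple[list[int], list[int]]:
    nA, nB = [], []
    for row in rows:
        a = 0
        for g in row:
            if g == "AA":
                a += 2
            elif g == "AB":
                a += 1
            elif g != "BB":
                raise ValueError(f"unknown genotype symbol {g!r}")
        nA.append(a)
        nB.append(2 * len(row) - a)
    return nA, nB


def local_counts(case_rows: Sequence[Sequence[str]],
                 control_rows: Sequence[Sequence[str]]) -> SiteCounts:
    """Input-preparation phase of one site: allele counts per SNP.

    ``case_rows`` / ``control_rows`` are per-SNP sequences of genotypes in
    {AA, AB, BB}.  Runs with no interaction.
    """
    if len(case_rows) != len(control_rows):
        raise ValueError("case and control tables differ in SNP count")
    ncA, ncB = _count_group(case_rows)
    ntA, ntB = _count_group(control_rows)
    return SiteCounts(ncA, ncB, ntA, ntB,
                      Nc=len(case_rows[0]), Nt=len(control_rows[0]))


@dataclass(frozen=True)
class BitlengthSelection:
    """Minimum operand bitlengths guaranteeing correctness.

    ``ell1`` bounds the comparison in the MAF minimum: the extreme is a
    monomorphic SNP with max(nA, nB) = N', and the comparison protocol needs
    one extra bit, hence ceil(log2 N') + 1.  ``ell2_base`` bounds the
    chi-squared division operands before precision scaling: the numerator
    peaks at (N'_c N'_t)^2, giving 2(log2 N'_c + log2 N'_t) bits; integer
    division additionally carries the k_bits of the precision factor.
    """

    ell1: int
    ell2_base: int
    ell2_int: int
    ell2_float: int


def compute_bitlengths(Nc: int, Nt: int, *, k_bits: int = 21,
                       precision_bits: int = 21) -> BitlengthSelection:
    if Nc < 1 or Nt < 1:
        raise ValueError("group sizes must be >= 1")
    n_prime = 2 * (Nc + Nt)
    ell1 = math.ceil(math.log2(n_prime)) + 1
    ell2_base = math.ceil(2 * (math.log2(2 * Nc) + math.log2(2 * Nt)))
    return BitlengthSelection(ell1=ell1, ell2_base=ell2_base,
                              ell2_int=ell2_base + k_bits,
                              ell2_float=precision_bits)


@dataclass
class GwasResult:
    """Per-SNP MAF and chi-squared; monomorphic SNPs have chisq None."""

    maf: list[Fraction]
    chisq: list[Fraction | float | None]
    res1: list[int] = field(default_factory=list)
    res2: list[int] = field(default_factory=list)


def _aggregate(c1: SiteCounts, c2: SiteCounts):
    if c1.n_snps != c2.n_snps:
        raise ValueError("sites disagree on SNP count")
    P = c1.n_snps
    ncA = [c1.ncA[j] + c2.ncA[j] for j in range(P)]
    ncB = [c1.ncB[j] + c2.ncB[j] for j in range(P)]
    ntA = [c1.ntA[j] + c2.ntA[j] for j in range(P)]
    ntB = [c1.ntB[j] + c2.ntB[j] for j in range(P)]
    return ncA, ncB, ntA, ntB


def clear_gwas(c1: SiteCounts, c2: SiteCounts) -> GwasResult:
    """Exact rational evaluation of both statistics (the oracle path)."""
    ncA, ncB, ntA, ntB = _aggregate(c1, c2)
    Nc = 2 * (c1.Nc + c2.Nc)
    Nt = 2 * (c1.Nt + c2.Nt)
    n_prime = Nc + Nt
    maf, chisq = [], []
    for j in range(len(ncA)):
        nA = ncA[j] + ntA[j]
        nB = ncB[j] + ntB[j]
        maf.append(Fraction(min(nA, nB), n_prime))
        d = (ncA[j] * ntB[j] - ncB[j] * ntA[j]) ** 2
        c = nA * nB
        chisq.append(Fraction(d * n_prime, Nc * Nt * c) if c > 0 else None)
    return GwasResult(maf=maf, chisq=chisq)


def share_counts(be, counts: SiteCounts) -> dict[str, list]:
    """Input-preparation step: one site's count vectors as shared columns."""
    return {key: be.input_vec(getattr(counts, key))
            for key in ("ncA", "ncB", "ntA", "ntB")}


def secure_maf(be, shared1: dict, shared2: dict, ell1: int) -> list:
    """Shared res1 = min(n_A, n_B) per SNP over both sites and groups.

    One batched comparison and one batched multiplication for the whole
    panel; the public division by N' happens after reconstruction.
    """
    nA = be.sum_vec([shared1["ncA"], shared1["ntA"],
                     shared2["ncA"], shared2["ntA"]])
    nB = be.sum_vec([shared1["ncB"], shared1["ntB"],
                     shared2["ncB"], shared2["ntB"]])
    b = be.lt_vec(nA, nB, ell1)
    return be.add_vec(be.mult_vec(b, be.sub_vec(nA, nB)), nB)


def secure_chisq(be, shared1: dict, shared2: dict, sel: BitlengthSelection,
                 c_bits: int, *, division: str = "int", k_bits: int = 21,
                 precision_bits: int = 21):
    """Shared scaled chi-squared numerator/denominator reduction per SNP.

    Returns res2 column with reconstruct(res2) = floor(k d / c) for the
    integer path, or a (significand, exponent) column pair for the
    floating-point variant.  The three independent products share one
    round; the caller applies the public scale N'/(k N'_c N'_t) after
    reconstruction.
    """
    ncA = be.sum_vec([shared1["ncA"], shared2["ncA"]])
    ncB = be.sum_vec([shared1["ncB"], shared2["ncB"]])
    ntA = be.sum_vec([shared1["ntA"], shared2["ntA"]])
    ntB = be.sum_vec([shared1["ntB"], shared2["ntB"]])
    P = len(ncA)
    left = ncA + ncB + be.add_vec(ncA, ntA)
    right = ntB + ntA + be.add_vec(ncB, ntB)
    prod = be.mult_vec(left, right)
    a_, b_, cden = prod[:P], prod[P:2 * P], prod[2 * P:]
    diff = be.sub_vec(a_, b_)
    d = be.mult_vec(diff, diff)
    if division == "int":
        kd = be.affine_vec(d, 1 << k_bits, 0)
        return be.div_vec(kd, cden, sel.ell2_int, y_bits=c_bits)
    if division == "float":
        return be.float_div_vec(d, cden, precision_bits,
                                d_bits=sel.ell2_base, c_bits=c_bits)
    raise ValueError(f"unknown division mode {division!r}")


def run_gwas(c1: SiteCounts, c2: SiteCounts, *, backend: str = "secure",
             division: str = "int", k_bits: int = 21, precision_bits: int = 21,
             kappa: int = 40, seed: int | None = None,
             ctx: MpcContext | None = None) -> GwasResult:
    """Execute the secure GWAS protocol end to end and reconstruct.

    ``division`` selects the mandatory integer-division path ("int",
    chi-squared exact to one k-scaled unit) or the floating-point variant
    ("float", relative error <= 2**(1-precision_bits)).  Monomorphic SNPs
    (both alleles never observed together) make the chi-squared denominator
    zero; the division contract requires a positive divisor, so callers must
    pre-filter them — the synthetic generator guarantees polymorphic SNPs.

    The sharing modulus is sized to the largest masked-protocol operand
    (division comparisons reach ~2x the operand bitlength), which exceeds
    the narrow modulus adequate for the MAF comparison alone.
    """
    Nc = c1.Nc + c2.Nc
    Nt = c1.Nt + c2.Nt
    n_prime = 2 * (Nc + Nt)
    sel = compute_bitlengths(Nc, Nt, k_bits=k_bits, precision_bits=precision_bits)
    c_bits = (4 * Nc * Nt).bit_length()  # denominator c <= N'_c * N'_t
    if division == "int":
        f = sel.ell2_int
        ell_max = max(sel.ell1, f, c_bits + f - 1)
    elif division == "float":
        s = precision_bits + 1 + max(0, c_bits - sel.ell2_base)
        ell_max = max(sel.ell1, sel.ell2_base + s, c_bits)
    else:
        raise ValueError(f"unknown division mode {division!r}")
    if ctx is None:
        ctx = MpcContext.for_bitlength(ell_max, kappa=kappa, seed=seed)
    be = make_backend(backend, ctx)

    # input preparation: each site shares its local counts
    shared1 = share_counts(be, c1)
    shared2 = share_counts(be, c2)

    res1 = secure_maf(be, shared1, shared2, sel.ell1)
    out2 = secure_chisq(be, shared1, shared2, sel, c_bits, division=division,
                        k_bits=k_bits, precision_bits=precision_bits)

    maf_vals = be.open_vec(res1)
    result = GwasResult(
        maf=[Fraction(v, n_prime) for v in maf_vals],
        chisq=[], res1=list(maf_vals))
    scale = Fraction(n_prime, (2 * Nc) * (2 * Nt))
    if division == "int":
        vals = be.open_vec(out2)
        result.res2 = list(vals)
        result.chisq = [Fraction(v, 1 << k_bits) * scale for v in vals]
    else:
        q, E = out2
        qv = be.open_vec(q)
        Ev = be.open_signed_vec(E)
        result.res2 = list(qv)
        result.chisq = [float(Fraction(x, 1) * Fraction(2) ** e * scale)
                        for x, e in zip(qv, Ev)]
    return result


def run_gwas_from_genotypes(site1_case, site1_control, site2_case,
                            site2_control, **kwargs) -> GwasResult:
    """Convenience wrapper: local counting at both sites, then the protocol."""
    c1 = local_counts(site1_case, site1_control)
    c2 = local_counts(site2_case, site2_control)
    return run_gwas(c1, c2, **kwargs)
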