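# Methods

This note documents the models, protocol realizations, parameter choices
and numerical conventions of `genoshare`, and what the synthetic-data
suites do and do not establish.

## Setting and trust model

Three computational parties evaluate all protocols on (3,1)-threshold
Shamir shares over a prime field GF(p); the two data owners provide shares
and reconstruct outputs.  Security is semi-honest: parties follow the
protocol and do not collude.  Any single share is marginally uniform on
[0, p), so one party learns nothing; two shares determine a secret.
Evaluation points are fixed at x = 1, 2, 3, giving constant Lagrange
coefficients (3, -3, 1) at zero.

The parties are simulated in one process under a synchronous round
scheduler.  A *round* is one all-to-all message exchange; the per-context
transcript records every round with its message count and payload size, and
the test suite asserts the round-structure claims (batching, locality of
linear operations) against it.  Real network transport and malicious
security are out of scope.

## Building-block realizations

Multiplication is the classic degree-reduction protocol: parties multiply
shares locally (points of a degree-2 polynomial) and re-share; the new
share is the Lagrange-weighted sum of received sub-shares.  One round per
batch, regardless of batch size.

Comparison, equality, bit decomposition and division are built from
*statistically masked openings*: a preprocessing (dealer) phase supplies
Shamir-shared uniformly random bits and bounded random field elements; the
online phase opens `value + mask`, which is statistically indistinguishable
from uniform up to 2^-kappa (kappa defaults to 40 bits), and finishes with
local affine steps plus logarithmic-depth trees of batched
multiplications:

* `EQ(x, y, ell)`: open `c = (x - y) + r_low + 2^ell r_hi`; the secrets are
  equal iff `c = r_low (mod 2^ell)`, tested as an AND-tree over bitwise
  agreements of public `c` with the shared bits of `r_low`.  Errs with
  probability <= 2^-kappa (mask wrap).
* `LT(x, y, ell)`: the sign of `z = x - y + 2^ell` is bit `ell` of `z`,
  isolated by a masked mod-2^ell reduction; the borrow bit of the public
  remainder against the shared mask bits comes from a suffix-OR
  (prefix computation, one batched multiplication per doubling level).
  Deterministically correct; the masking is only for privacy.
* `Div(x, y, f)`: oblivious restoring long division — f iterations of one
  comparison and one multiplication, yielding the exact floor quotient.
  Callers may pass tighter public bounds on the divisor and quotient
  bitlengths; the chi-squared path does (its denominator is bounded by
  `N'_c N'_t`).
* Floating-point division: both operands are obliviously normalised
  (bit decomposition via a masked opening and a carry-lookahead
  subtraction circuit, then a most-significant-bit prefix), the
  significand quotient is an integer division at `precision+1+max(0,
  c_bits-d_bits)` scale bits, and the result is a shared
  (significand, exponent) pair with relative error <= 2^(1-precision).
  Default precision 21 bits.  This is the optional path; integer division
  is the correctness default.
* `OR`/`XOR` of shared bits reuse a single multiplication;
  cross-modulus conversion opens a masked value under the source modulus
  and subtracts the (dealer-correlated) mask re-shared under the target
  modulus — one round.

Preprocessed randomness is modelled as an offline phase and not charged to
the online round transcript (the standard offline/online accounting);
openings and multiplications are charged.  Every vectorised operation is
batched: m parallel instances cost the same rounds as one.

Every protocol also runs over a *cleartext backend* that evaluates the same
operations on plain integers while charging the identical round structure.
It is the oracle twin for correctness tests and the fast path for
large randomized suites.

## Moduli and bitlengths

Masked protocols need `p > 2^(ell_max + kappa + 2)` for the largest operand
bitlength `ell_max` under a modulus.  Three named defaults are provided:
just above 2^84 (GWAS comparison/floating-point configuration), 2^118
(wide Hamming modulus) and 2^85 (narrow SNP&SUB modulus).  The Hamming
defaults satisfy the invariant for their protocols at the default encoding
parameters and are used as-is.  The GWAS integer-division path compares
intermediate remainders against shifted divisors of up to ~2x the operand
bitlength, so its runner sizes the context prime directly from the
invariant (about 2^117 at a 200+200 cohort) rather than using the narrow
default; every modulus is configurable.

Operand bitlengths are selected to their minima: the MAF comparison uses
`ell1 = ceil(log2 N') + 1` (the extreme being a monomorphic SNP with
`max(n_A, n_B) = N'`, plus the comparison protocol's extra bit — 11 bits at
a 200+200 cohort); the chi-squared division uses
`ell2 = ceil(2(log2 N'_c + log2 N'_t))` (35 bits at that cohort) plus the
`|k| = 21` precision bits for the integer path, while the floating-point
path needs only the requested precision.

## GWAS protocol

Three phases.  Input preparation: each site counts alleles per SNP locally
(`n_cA, n_cB, n_tA, n_tB`) and shares the counts.  Execution: aggregation
across sites is local (linear); the minimum for MAF is one comparison and
one multiplication; the chi-squared numerator/denominator products run in
a single round (they are independent), followed by one square and the
division of the `k`-scaled numerator.  Reconstruction: the output party
applies the public scalings `res1 / N'` and `res2 N' / (k N'_c N'_t)`.
With `k = 2^21` the integer path is exact to one `2^-21` floor unit.

A monomorphic SNP makes the denominator zero.  The cleartext oracle flags
it (None/NaN); the secure path requires a positive divisor, so callers
pre-filter monomorphic sites (the synthetic generator redraws them) —
a secure zero-test would add rounds for a case excluded by standard GWAS
quality control anyway.

## Hamming distance protocol

Record encoding: `V1 = chrom_index * L + POS` with chromosomes indexed
1-22, X=23, Y=24 and `L = 250,000,000` (above the longest human
chromosome); dummies carry `V1 = 25L + 1` and therefore sort last.  REF and
ALT are packed 2 bits per base, left-justified and zero-padded to the
public maximum length `M` (default 100), with the *character count*
appended in `ceil(log2(M+1))` bits — appending the count is what keeps the
encoding injective across lengths (a prefix and its extension differ in the
suffix), and a count field is the reading of the "length suffix"
convention consistent with the stated `2M + log M` bit budget; the
exhaustive injectivity test fixes it.  When the encoding exceeds what the
modulus can mask (207 bits at M=100), it is split into equal blocks
(three at the defaults) compared block-wise and AND-ed.

The compact SNP&SUB encoding maps single-character fields to 0-3 and
longer fields to 4 (guaranteeing inequality against any single character)
and adds the type bit V4; it runs under the narrow modulus.

Padding: `basic`/`split` pad to a combined power of two
(`q = ceil(log2(alpha (N1+N2) + 2))`, `alpha = 1`; `q_s` with
`alpha_s = 0.3` for SUB sets); each site first pads to
`floor(alpha N_i) + 1` and the remaining budget goes to site 1 (a public
convention).  The generalised-merge schemes pad each set only to
`floor(alpha N_i) + 1`.  At least one dummy per set is required; a public
target below the actual relevant-record count is a padding-infeasibility
error.  Dummy counts are secret-shared: the number of *relevant* records
is private even though dataset sizes are public.

Scans: the merged set is examined pairwise with batched equality tests.
In the basic scan, a new location adds 1 and a repetition retracts it
unless REF agrees and ALT differs; dummies contribute `d1 + d2 - 2`,
corrected with the shared dummy counts.  The SNP&SUB scan weights
contributions by the type bits and subtracts the equal-location,
different-type pair count, which exactly compensates the double count the
SUB pass introduced.  The generalised-merge scan ignores equal-key pairs
(merge duplicates) and treats keys differing by exactly 1 as location
matches — the `4 V1` / `4 V1 + 1` transform (applied to shares by local
public scaling) makes both conditions precise, and makes dummies
self-cancel without a correction term.

One detail absent from the source algorithms: the SNP&SUB sub-distance can
be transiently *negative* (its compensation term can exceed its positive
part, e.g. a single location typed SUB in one set and SNP in the other
with differing REF).  The cross-modulus conversion contract requires a
small non-negative value, so the combined schemes shift it by a public
offset (the merged set size + 2) before conversion and subtract the offset
afterwards.

Ties in the compare-and-exchange follow the printed formula: with equal
keys the strict comparison yields c = 0 and the two records trade slots
(each keeps its own fields).  No scheme's result depends on intra-tie
order, which the randomized oracle suites confirm.

## Generalised merge

The classic odd-even merge concatenates the two sorted inputs with the
second reversed and applies strides halving from (m+n)/2 to 1; it needs a
power-of-two total.  The generalisation pads *during* execution: whenever a
current sublist has odd length (and more than one element), a copy of its
entire last record is appended before that stride's exchanges.  Appending a
copy of the last element preserves the rise-then-fall shape of a sublist,
so the half-cleaner invariant (every element of the first half <= every
element of the second) continues to hold and the recursion sorts each half;
the output is therefore sorted, contains every input record, and its
surplus consists only of copies — never more than the next power of two in
total.  Singleton sublists are never padded.  When no odd sublist arises,
the schedule coincides with the classic merge.

## Synthetic data

The GWAS generator draws a per-SNP minor-allele frequency uniformly from a
configurable range (default 0.05-0.5) and samples genotypes as two
independent allele draws per individual (Hardy-Weinberg), partitioned over
two sites and case/control groups; panel-monomorphic SNPs are redrawn.  It
does not model linkage disequilibrium, genotyping error, missingness or
population structure — irrelevant to protocol correctness, which is
per-SNP and exact, but a reason the suites say nothing about statistical
power on real panels.

The VCF generator controls location overlap between the two sets, the SUB
fraction (capped at the public bound `floor(alpha_s N_i)` so padding is
always feasible), the fraction of shared locations typed SUB in one set
and SNP in the other, the fraction of shared locations with equal REF and
differing ALT, and a fraction of DEL/INS records that exercise filtering;
locations are unique per dataset as the distance rule requires.  Generated
instances hit every branch of the distance rule (asserted).  Positions are
uniform, not drawn from real variant densities; REF/ALT strings are short
uniform nucleotide strings — again immaterial to correctness, which is
exact integer computation, but not a model of real variant spectra.

Both generators are deterministic under a fixed seed and bundle truth
values computed by the cleartext oracles, so protocol tests never trust
generator bookkeeping.

## Problem sizes in the test suite

Correctness of the secure backends is established at three layers, chosen
to keep the default suite in the minutes range on one CPU: (i) primitive
oracle equivalence (exhaustive 4-bit comparison domains, hundreds of
randomized multiplication/division/conversion trials); (ii) secure-vs-
cleartext equivalence of merges and of every distance scheme on small
instances (set sizes up to ~16); (iii) one batched secure GWAS run over a
200-SNP partitioned panel checked exactly against the rational oracle.
The large randomized Hamming families (100+ pairs per scheme, set sizes to
64, all overlap regimes and forced type mismatches) run the identical
scheme code over the cleartext backend, whose primitive-for-primitive
agreement with the secure backend is what layers (i)-(ii) establish.

## Known limitations

* Semi-honest, non-colluding three-party model only; no verifiable
  sharing, no malicious security, no real sockets.
* The comparison/equality protocols err with probability <= 2^-kappa per
  invocation (mask wrap); kappa = 40 makes this negligible but nonzero.
* Chromosome labels outside 1-22/X/Y are rejected (or skipped on request
  at read time); records at one location with two types within a single
  dataset are an input error, as the distance rule presupposes.
* The hash-based constant-width REF/ALT representation for very large M
  and generalized bitonic sorting without duplication are not implemented;
  edit distance is out of scope.
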