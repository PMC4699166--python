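# genoshare

Secure three-party computation of GWAS statistics and of a genomic Hamming
distance over secret-shared variant data.

Two institutions each hold sensitive genomic data — a horizontally
partitioned case/control genotype panel, or a personal variant set in VCF —
and want joint statistics without revealing anything beyond the agreed
output.  `genoshare` implements this with an (n=3, t=1)-threshold Shamir
secret-sharing scheme over a prime field: the two data owners split their
values into shares held by three computational parties (simulated in one
process under a synchronous round scheduler), all computation is
data-oblivious on shares, and only the final statistic is reconstructed.
The adversary model is semi-honest, non-colluding parties.

## What it computes

**GWAS task.** For each SNP, with allele counts `n_A = 2 n_AA + n_AB`,
`n_B = 2 n_BB + n_AB` aggregated over both groups and both sites,
`N' = 2N`, `N'_c = 2 N_c`, `N'_t = 2 N_t`:

* minor allele frequency `MAF = min(n_A, n_B) / N'`, computed on shares as
  `res1 = LT(n_A, n_B) * (n_A - n_B) + n_B` with the public division by `N'`
  deferred to reconstruction;
* the allele-count chi-squared
  `X^2 = (n_cA n_tB - n_cB n_tA)^2 N' / (N'_c N'_t (n_cA + n_tA)(n_cB + n_tB))`,
  reduced on shares to three parallel products, one square and one integer
  division of the k-scaled numerator (`k = 2^21` by default; a
  floating-point division variant with relative error `<= 2^-20` is
  available behind a flag).

All P SNPs run in single batches, so the number of communication rounds is
independent of P.

**Hamming task.** Between two VCF-derived record sets (types SUB/SNP only):
+1 for every location `<CHROM, POS>` in exactly one set, +1 for every shared
location with equal REF and differing ALT.  Records are encoded as integers
(`V1 = chrom * L + POS`; REF/ALT packed 2 bits per base with a length
suffix), padded with dummies to public sizes, secret-shared, obliviously
merged with a compare-and-exchange network, and scanned pairwise with
batched equality tests.  Four schemes trade off padding and bitlengths:
`basic`, `split` (separate SUB and SNP&SUB passes under wide/narrow moduli
with cross-modulus recombination), `newmerge` (a generalisation of the
Batcher odd-even merge to arbitrary input sizes via per-iteration
duplication of the last record of odd sublists, plus a `4*V1 / 4*V1+1`
location transform that neutralises the duplicates), and `full` (both).

## Worked example

```
$ genoshare synth-gwas -o panel -P 5 --nc1 4 --nc2 4 --nt1 4 --nt2 4 --seed 3
wrote panel of 5 SNPs to panel
$ genoshare gwas panel/site1_case.tsv panel/site1_control.tsv \
      panel/site2_case.tsv panel/site2_control.tsv -o gwas.tsv --seed 1
wrote 5 SNPs to gwas.tsv
$ cat gwas.tsv
snp_id  maf      chisq
snp0000 0.15625  0.23703700304031372
snp0001 0.3125   0.581818163394928
snp0002 0.5      0.5
snp0003 0.21875  1.645714282989502
snp0004 0.34375  3.4632034301757812
```

Each row is one SNP: `maf` is the reconstructed minimum-allele frequency
(here 8+8 cases and 8+8 controls, so `N' = 64`; e.g. `0.15625 = 10/64`
means the rarer allele was observed 10 times), and `chisq` is the
reconstructed association statistic — identical, up to one `2^-21` floor
unit, to the cleartext chi-squared on the pooled allele table
(`genoshare oracle gwas ...` prints the oracle values for comparison).

```
$ genoshare synth-vcf -o pair --n1 12 --n2 9 --seed 5
wrote VCF pair (truth distance 13) to pair
$ genoshare hamming pair/s1.vcf pair/s2.vcf --scheme full --seed 2
13
$ genoshare oracle hamming pair/s1.vcf pair/s2.vcf
13
```

The secure run reconstructs exactly the distance the cleartext rule
computes; `--result-file` additionally records the padded set sizes and the
round/message counts of the simulated protocol (161 rounds, 966 messages
for this instance).

## Layout

| module                  | contents                                                        |
| ----------------------- | --------------------------------------------------------------- |
| `genoshare.sharing`     | prime fields, Shamir share/reconstruct/lincomb, round transcript|
| `genoshare.primitives`  | Mult, EQ, LT, Div, float division, OR/XOR, modulus conversion; secure + cleartext backends |
| `genoshare.merge`       | compare-and-exchange, Batcher odd-even merge, generalised merge |
| `genoshare.gwas`        | local allele counting, bitlength selection, secure MAF and chi-squared, exact oracle |
| `genoshare.hamming`     | record filtering/encoding/padding, the distance oracle, four secure schemes |
| `genoshare.io_files`    | genotype TSV and VCF readers/writers                            |
| `genoshare.synth`       | seeded generators for both input kinds with bundled truth       |
| `genoshare.cli`         | `genoshare` command-line entry point                            |

See `docs/methods.md` for the protocol realizations, parameter defaults,
and the limitations of the synthetic data.
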