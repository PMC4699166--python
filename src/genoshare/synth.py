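"""Synthetic inputs for both tasks, with bundled cleartext truth.

The GWAS generator emulates a two-site case/control panel: each SNP gets a
minor-allele frequency drawn from a configurable range and genotypes are
two independent allele draws per individual (Hardy-Weinberg sampling).
SNPs that come out monomorphic across the whole panel are redrawn so the
chi-squared denominator is always positive.

The VCF generator emulates the variant-set comparison inputs: two record
sets with controllable location overlap, SUB fraction, REF/ALT agreement
patterns at shared locations, SUB-vs-SNP type disagreements at shared
locations, and a sprinkling of DEL/INS records that the distance rule must
filter out.  Bundled truth values are computed with the cleartext oracles
(:func:`genoshare.gwas.clear_gwas`, :func:`genoshare.hamming.hd_clear`) so
protocol tests never have to trust the generator's bookkeeping.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .gwas import GwasResult, SiteCounts, clear_gwas, local_counts
from .hamming import CHROM_INDEX, EncodingParams, VariantRecord, hd_clear

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# GWAS


@dataclass(frozen=True)
class SynthGwasSpec:
    """Panel shape: P SNPs; case/control group sizes per site."""

    P: int = 100
    nc1: int = 50
    nc2: int = 50
    nt1: int = 50
    nt2: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        if min(self.P, self.nc1, self.nc2, self.nt1, self.nt2) < 1:
            raise ValueError("all sizes must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")


@dataclass
class GwasDataset:
    site1_case: pd.DataFrame
    site1_control: pd.DataFrame
    site2_case: pd.DataFrame
    site2_control: pd.DataFrame
    truth: GwasResult = field(repr=False, default=None)

    def site_counts(self) -> tuple[SiteCounts, SiteCounts]:
        c1 = local_counts(self.site1_case.values.tolist(),
                          self.site1_control.values.tolist())
        c2 = local_counts(self.site2_case.values.tolist(),
                          self.site2_control.values.tolist())
        return c1, c2


def _genotype(rng: random.Random, freq: float) -> str:
    a = (rng.random() < freq) + (rng.random() < freq)
    return ("BB", "AB", "AA")[a]


def synth_gwas(spec: SynthGwasSpec) -> GwasDataset:
    rng = random.Random(spec.seed)
    sizes = (spec.nc1, spec.nt1, spec.nc2, spec.nt2)
    rows: list[list[list[str]]] = [[] for _ in sizes]
    for _ in range(spec.P):
        while True:
            freq = rng.uniform(*spec.maf_range)
            snp_rows = [[_genotype(rng, freq) for _ in range(n)] for n in sizes]
            flat = [g for row in snp_rows for g in row]
            n_a = sum(2 * (g == "AA") + (g == "AB") for g in flat)
            if 0 < n_a < 2 * len(flat):  # redraw monomorphic SNPs
                break
        for group, row in zip(rows, snp_rows):
            group.append(row)
    snp_ids = [f"snp{i:04d}" for i in range(spec.P)]

    def frame(data, prefix, n):
        return pd.DataFrame(data, index=snp_ids,
                            columns=[f"{prefix}{j:03d}" for j in range(n)])

    ds = GwasDataset(
        site1_case=frame(rows[0], "s1c", spec.nc1),
        site1_control=frame(rows[1], "s1t", spec.nt1),
        site2_case=frame(rows[2], "s2c", spec.nc2),
        site2_control=frame(rows[3], "s2t", spec.nt2),
    )
    ds.truth = clear_gwas(*ds.site_counts())
    return ds


# ---------------------------------------------------------------------------
# VCF pairs


@dataclass(frozen=True)
class SynthVcfSpec:
    """Shape of one pair of variant sets.

    Fractions are of the relevant (SUB/SNP) records: ``overlap`` controls
    shared locations, ``sub_fraction`` targets the public alpha_s bound,
    ``type_mismatch_fraction`` types shared locations SUB in one set and
    SNP in the other, ``ref_equal_alt_differ_fraction`` makes shared
    locations count toward the distance; ``irrelevant_fraction`` adds
    DEL/INS records that must be filtered out.
    """

    n1: int = 30
    n2: int = 30
    overlap: float = 0.5
    sub_fraction: float = 0.3
    type_mismatch_fraction: float = 0.1
    ref_equal_alt_differ_fraction: float = 0.5
    irrelevant_fraction: float = 0.1
    max_len: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("overlap", "sub_fraction", "type_mismatch_fraction",
                     "ref_equal_alt_differ_fraction", "irrelevant_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("record counts must be >= 1")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")


@dataclass
class VcfPair:
    records1: list[VariantRecord]
    records2: list[VariantRecord]
    truth: int
    branch_hits: dict


def _string(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _other_string(rng: random.Random, s: str) -> str:
    while True:
        t = _string(rng, len(s))
        if t != s:
            return t


def synth_vcf_pair(spec: SynthVcfSpec,
                   params: EncodingParams | None = None) -> VcfPair:
    """Generate one dataset pair plus its oracle distance.

    The requested overlap, SUB and mismatch fractions are realised within
    one record (rounding); locations are unique within and across datasets
    except for the deliberately shared ones.
    """
    params = params or EncodingParams()
    rng = random.Random(spec.seed)

    irr1 = round(spec.irrelevant_fraction * spec.n1)
    irr2 = round(spec.irrelevant_fraction * spec.n2)
    r1, r2 = spec.n1 - irr1, spec.n2 - irr2
    if r1 < 1 or r2 < 1:
        raise ValueError("irrelevant_fraction leaves no relevant records")
    n_shared = round(spec.overlap * min(r1, r2))
    n_mismatch = round(spec.type_mismatch_fraction * n_shared)

    locations: set[tuple[str, int]] = set()

    def new_loc() -> tuple[str, int]:
        while True:
            chrom = rng.choice(list(CHROM_INDEX))
            pos = rng.randrange(1, params.L + 1)
            if (chrom, pos) not in locations:
                locations.add((chrom, pos))
                return chrom, pos

    # cap SUB counts at the public padding bound floor(alpha_s * N_i) so the
    # SUB sets can always take at least one dummy record
    sub_target1 = min(round(spec.sub_fraction * r1),
                      math.floor(spec.sub_fraction * spec.n1))
    sub_target2 = min(round(spec.sub_fraction * r2),
                      math.floor(spec.sub_fraction * spec.n2))
    subs_used1 = subs_used2 = 0
    recs1: list[VariantRecord] = []
    recs2: list[VariantRecord] = []

    def make(chrom, pos, svtype, ref, alt):
        return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                             svtype=svtype)

    def sub_strings():
        n = rng.randrange(2, spec.max_len + 1) if spec.max_len > 1 else 1
        return _string(rng, n)

    for i in range(n_shared):
        chrom, pos = new_loc()
        mismatch = i < n_mismatch
        if mismatch:
            t1, t2 = ("SUB", "SNP") if i % 2 == 0 else ("SNP", "SUB")
            # respect the public SUB bound; flip or downgrade if saturated
            if t1 == "SUB" and subs_used1 >= sub_target1:
                t1, t2 = t2, t1
            if t2 == "SUB" and subs_used2 >= sub_target2:
                if t1 == "SNP" and subs_used1 < sub_target1:
                    t1, t2 = t2, t1
                else:
                    t1 = t2 = "SNP"
        else:
            want_sub = (subs_used1 < sub_target1 and subs_used2 < sub_target2
                        and rng.random() < spec.sub_fraction)
            t1 = t2 = "SUB" if want_sub else "SNP"
        # single-character alleles whenever a SNP is involved, so the pair
        # genuinely shares a location with comparable fields
        single = "SNP" in (t1, t2)
        ref1 = _string(rng, 1) if single else sub_strings()
        if rng.random() < spec.ref_equal_alt_differ_fraction:
            ref2 = ref1
            alt1 = _other_string(rng, ref1)
            alt2 = _other_string(rng, alt1)
            while alt2 == ref2:
                alt2 = _other_string(rng, alt1)
        elif rng.random() < 0.5:
            ref2, alt1 = ref1, _other_string(rng, ref1)
            alt2 = alt1
        else:
            ref2 = _other_string(rng, ref1)
            alt1 = _other_string(rng, ref1)
            alt2 = _other_string(rng, ref2)
        recs1.append(make(chrom, pos, t1, ref1, alt1))
        recs2.append(make(chrom, pos, t2, ref2, alt2))
        subs_used1 += t1 == "SUB"
        subs_used2 += t2 == "SUB"

    def fill_unique(recs, total, subs_used, sub_target):
        while len(recs) < total:
            chrom, pos = new_loc()
            if subs_used < sub_target:
                subs_used += 1
                s = sub_strings()
                recs.append(make(chrom, pos, "SUB", s, _other_string(rng, s)))
            else:
                ref = _string(rng, 1)
                recs.append(make(chrom, pos, "SNP", ref,
                                 _other_string(rng, ref)))
        return subs_used

    fill_unique(recs1, r1, subs_used1, sub_target1)
    fill_unique(recs2, r2, subs_used2, sub_target2)

    for recs, n_irr in ((recs1, irr1), (recs2, irr2)):
        for j in range(n_irr):
            chrom, pos = new_loc()
            if j % 2 == 0:
                ref = _string(rng, max(2, min(3, spec.max_len)))
                recs.append(make(chrom, pos, "DEL", ref, ref[0]))
            else:
                alt = _string(rng, max(2, min(3, spec.max_len)))
                recs.append(make(chrom, pos, "INS", alt[0], alt))

    rng.shuffle(recs1)
    rng.shuffle(recs2)
    hits: dict = {}
    truth = hd_clear(recs1, recs2, branch_hits=hits)
    return VcfPair(records1=recs1, records2=recs2, truth=truth,
                   branch_hits=hits)
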