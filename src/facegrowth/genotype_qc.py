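"""SNP-level quality control: call rate, MAF, exact Hardy-Weinberg test.

Dosages are ALT-allele counts 0/1/2 with -1 encoding a missing call.
Filtering keeps a SNP iff call rate >= 0.98, MAF >= 0.10 and the exact
Hardy-Weinberg p-value is strictly greater than 1e-4 (inclusive bounds
on the first two, strict on the last).  MAF is computed from called
genotypes only; missing calls are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "MISSING",
    "VariantStats",
    "variant_stats",
    "hwe_exact",
    "filter_variants",
    "read_vcf",
    "read_plink",
]

MISSING = -1

DEFAULT_CALL_RATE_MIN = 0.98
DEFAULT_MAF_MIN = 0.10
DEFAULT_HWE_P_MIN = 1e-4


@dataclass
class VariantStats:
    snp_id: str
    n_samples: int
    n_called: int
    n_AA: int  # dosage 0 (hom ref)
    n_Aa: int  # dosage 1 (het)
    n_aa: int  # dosage 2 (hom alt)
    call_rate: float
    maf: float
    hwe_p: float
    passed: bool = True
    fail_reasons: list[str] = field(default_factory=list)

    @property
    def computable(self) -> bool:
        return self.n_called > 0


def variant_stats(dosages: np.ndarray, snp_id: str = "") -> VariantStats:
    """Per-SNP genotype counts, call rate, MAF and exact HWE p-value."""
    d = np.asarray(dosages)
    valid = (d == 0) | (d == 1) | (d == 2) | (d == MISSING)
    if not valid.all():
        bad = np.unique(d[~valid])
        raise ValueError(f"dosages must be 0/1/2/{MISSING}; got {bad.tolist()}")
    n_samples = d.size
    n_AA = int((d == 0).sum())
    n_Aa = int((d == 1).sum())
    n_aa = int((d == 2).sum())
    n_called = n_AA + n_Aa + n_aa
    call_rate = n_called / n_samples if n_samples else 0.0
    if n_called == 0:
        return VariantStats(snp_id, n_samples, 0, 0, 0, 0, call_rate,
                            maf=float("nan"), hwe_p=float("nan"),
                            passed=False, fail_reasons=["no_calls"])
    f_alt = (n_Aa + 2 * n_aa) / (2 * n_called)
    maf = min(f_alt, 1.0 - f_alt)
    p = hwe_exact(n_AA, n_Aa, n_aa)
    return VariantStats(snp_id, n_samples, n_called, n_AA, n_Aa, n_aa,
                        call_rate, maf, p)


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int, *, midp: bool = False) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all
    heterozygote counts ``h`` attainable with those allele counts, the
    exact probabilities ``P(h)`` with ``P(h) <= P(observed)``.  With
    ``midp`` only half the observed outcome's probability is counted.

    The exact probability of ``h`` heterozygotes given ``n`` genotypes
    and ``n_rare`` minor-allele copies is

        P(h) = n! / (n_hom_rare! h! n_hom_common!) * 2**h
               / [ (2n)! / (n_rare! n_common!) ]

    evaluated in log space; attainable ``h`` share the parity of
    ``n_rare``.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("no called genotypes")

    n_rare = min(n_Aa + 2 * n_aa, n_Aa + 2 * n_AA)
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(h) up to a constant shared by all h
    hom_rare = (n_rare - hs) // 2
    hom_common = n - hs - hom_rare
    logp = (hs * np.log(2.0)
            - gammaln(hom_rare + 1) - gammaln(hs + 1) - gammaln(hom_common + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hs == n_Aa]
    if p_obs.size != 1:
        raise ValueError(
            f"heterozygote count {n_Aa} unattainable for allele counts "
            f"({n_rare} rare / {2 * n} total)"
        )
    p_obs = float(p_obs[0])
    # small relative slack so float noise does not drop ties
    included = probs <= p_obs * (1.0 + 1e-12)
    p = float(probs[included].sum())
    if midp:
        p -= 0.5 * p_obs
    return min(p, 1.0)


def filter_variants(
    stats: list[VariantStats],
    call_rate_min: float = DEFAULT_CALL_RATE_MIN,
    maf_min: float = DEFAULT_MAF_MIN,
    hwe_p_min: float = DEFAULT_HWE_P_MIN,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the QC thresholds; returns (retained snp ids, exclusion log).

    Boundary conventions: call rate and MAF bounds are inclusive, the
    HWE bound is strict (a SNP with hwe_p exactly at the threshold is
    excluded).  Every exclusion is logged with all failing reasons.
    """
    retained: list[str] = []
    log_rows = []
    for st in stats:
        reasons = []
        if not st.computable:
            reasons.append("no_calls")
        else:
            if st.call_rate < call_rate_min:
                reasons.append(f"call_rate<{call_rate_min}")
            if st.maf < maf_min:
                reasons.append(f"maf<{maf_min}")
            if not (st.hwe_p > hwe_p_min):
                reasons.append(f"hwe_p<={hwe_p_min}")
        st.passed = not reasons
        st.fail_reasons = reasons
        if st.passed:
            retained.append(st.snp_id)
        else:
            log_rows.append((st.snp_id, st.call_rate, st.maf, st.hwe_p, ";".join(reasons)))
    log = pd.DataFrame(log_rows, columns=["snp_id", "call_rate", "maf", "hwe_p", "reasons"])
    return retained, log


def stats_frame(stats: list[VariantStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.snp_id, s.n_samples, s.n_called, s.n_AA, s.n_Aa, s.n_aa,
          s.call_rate, s.maf, s.hwe_p, s.passed, ";".join(s.fail_reasons))
         for s in stats],
        columns=["snp_id", "n_samples", "n_called", "n_AA", "n_Aa", "n_aa",
                 "call_rate", "maf", "hwe_p", "passed", "fail_reasons"],
    )


def read_vcf(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read biallelic GT dosages from a (plain-text or bgzipped) VCF.

    Returns (samples x SNPs int8 dosage matrix with -1 missing, variant
    metadata frame with snp_id/chrom/pos/ref/alt, sample ids).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    meta = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{var.ID or var.POS}: only biallelic sites supported")
        gt = np.asarray(var.gt_types, dtype=np.int8)  # gts012: 3 == unknown
        gt[gt == 3] = MISSING
        cols.append(gt)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0]))
    vcf.close()
    geno = (np.stack(cols, axis=1) if cols
            else np.empty((len(samples), 0), dtype=np.int8))
    variants = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return geno, variants, samples


def read_plink(ped_path, map_path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read PLINK-style text .ped/.map into dosages of the minor allele.

    The ALT (counted) allele per SNP is the lexicographically larger of
    the two alleles seen; ``0`` marks a missing allele.
    """
    variants = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )
    m = len(variants)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"ped row for {parts[0] if parts else '?'}: expected "
                    f"{6 + 2 * m} fields, got {len(parts)}"
                )
            samples.append(parts[1])
            alleles = parts[6:]
            rows.append(np.array(alleles, dtype=object).reshape(m, 2))
    if not rows:
        return np.empty((0, m), dtype=np.int8), variants, samples

    allele_mat = np.stack(rows)  # samples x m x 2
    geno = np.full((len(samples), m), MISSING, dtype=np.int8)
    ref_alleles, alt_alleles = [], []
    for j in range(m):
        a = allele_mat[:, j, :]
        seen = sorted(set(a.ravel()) - {"0"})
        if len(seen) > 2:
            raise ValueError(f"{variants['snp_id'][j]}: more than two alleles {seen}")
        ref = seen[0] if seen else "0"
        alt = seen[-1] if seen else "0"
        ref_alleles.append(ref)
        alt_alleles.append(alt)
        called = (a != "0").all(axis=1)
        geno[called, j] = (a[called] == alt).sum(axis=1)
    variants = variants.assign(ref=ref_alleles, alt=alt_alleles)
    return geno, variants[["snp_id", "chrom", "pos", "ref", "alt"]], samples
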