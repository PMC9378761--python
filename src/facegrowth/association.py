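"""Single-SNP association of the coded growth pattern (1-5).

The pattern code is treated as a quantitative trait in a simple linear
regression on allele dosage (intercept + slope, no covariates).  The
Wald p-value uses the t distribution with n - 2 degrees of freedom; the
likelihood-ratio p-value uses the Gaussian statistic n*ln(RSS0/RSS1)
against chi-square(1).  The Bonferroni-adjusted value is raw p times
the test count and is deliberately NOT capped at 1.  An ordinal-logit
test is available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_qc import MISSING

__all__ = [
    "SIGNIFICANT_P",
    "SUGGESTIVE_P",
    "DEFAULT_M_TESTS",
    "AssocResult",
    "wald_qtl",
    "lrt_qtl",
    "ordinal_qtl",
    "bonferroni_adjust",
    "format_2sf",
    "assign_tier",
    "run_association",
    "cluster_loci",
    "replication_select",
    "plot_manhattan",
    "plot_qq",
]

SIGNIFICANT_P = 5e-8
SUGGESTIVE_P = 1e-5
DEFAULT_M_TESTS = 800_000
DEFAULT_CLUSTER_WINDOW = 500_000

#: p-value reported for numerically perfect fits instead of exactly 0.
P_FLOOR = np.finfo(float).tiny

_RSS_REL_TOL = 1e-12


@dataclass
class AssocResult:
    beta: float
    se: float
    wald_p: float
    lrt_p: float
    n_used: int
    testable: bool = True
    degenerate: bool = False
    reason: str = ""


def _complete_pairs(codes, dosages) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(codes, dtype=float)
    g = np.asarray(dosages, dtype=float)
    if y.shape != g.shape:
        raise ValueError("codes and dosages must align")
    ok = ~np.isnan(y) & ~np.isnan(g) & (g != MISSING)
    return y[ok], g[ok]


def wald_qtl(codes, dosages) -> AssocResult:
    """Linear regression of code on dosage; Wald slope test.

    Missing genotypes (-1 or NaN) and missing codes are dropped
    pairwise.  A monomorphic dosage or constant phenotype yields an
    untestable result; a numerically perfect fit yields the p-value
    floor with the degenerate flag set.
    """
    y, g = _complete_pairs(codes, dosages)
    n = len(y)
    if n < 3:
        return AssocResult(np.nan, np.nan, np.nan, np.nan, n, False, False, "n<3")
    sxx = float(np.sum((g - g.mean()) ** 2))
    if sxx == 0.0:
        return AssocResult(np.nan, np.nan, np.nan, np.nan, n, False, False, "monomorphic")
    syy = float(np.sum((y - y.mean()) ** 2))
    if syy == 0.0:
        return AssocResult(np.nan, np.nan, np.nan, np.nan, n, False, False, "constant_phenotype")

    sxy = float(np.sum((g - g.mean()) * (y - y.mean())))
    beta = sxy / sxx
    rss1 = syy - beta * sxy
    if rss1 <= _RSS_REL_TOL * syy:
        return AssocResult(beta, 0.0, P_FLOOR, P_FLOOR, n, True, True, "perfect_fit")
    sigma2 = rss1 / (n - 2)
    se = math.sqrt(sigma2 / sxx)
    t = beta / se
    wald_p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    lrt_stat = n * math.log(syy / rss1)
    lrt_p = sps.chi2.sf(lrt_stat, df=1)
    return AssocResult(beta, se, max(wald_p, P_FLOOR), max(lrt_p, P_FLOOR), n)


def lrt_qtl(codes, dosages) -> float:
    """Likelihood-ratio p for the dosage slope (Gaussian working model)."""
    return wald_qtl(codes, dosages).lrt_p


def ordinal_qtl(codes, dosages) -> float:
    """Proportional-odds (ordinal logit) p-value for the dosage effect.

    Sensitivity check for treating the 1-5 code as quantitative; not
    part of the default pipeline output.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y, g = _complete_pairs(codes, dosages)
    if len(np.unique(y)) < 2 or np.ptp(g) == 0:
        return float("nan")
    endog = pd.Series(pd.Categorical(y, ordered=True))
    exog = pd.DataFrame({"dosage": g})
    model = OrderedModel(endog, exog, distr="logit")
    res = model.fit(method="bfgs", disp=False)
    return float(res.pvalues["dosage"])


def bonferroni_adjust(p: float, m_tests: int = DEFAULT_M_TESTS) -> float:
    """Bonferroni value = p * m_tests, uncapped (may far exceed 1)."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return p * m_tests


def format_2sf(x: float) -> float:
    """Round to two significant figures (table output convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.1e}")


def assign_tier(wald_p: float,
                significant_p: float = SIGNIFICANT_P,
                suggestive_p: float = SUGGESTIVE_P) -> str:
    """significant: p < 5e-8; suggestive: 5e-8 <= p < 1e-5; else none."""
    if not (0.0 < wald_p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {wald_p}")
    if wald_p < significant_p:
        return "significant"
    if wald_p < suggestive_p:
        return "suggestive"
    return "none"


def run_association(
    codes: pd.DataFrame,
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    *,
    m_tests: int = DEFAULT_M_TESTS,
    significant_p: float = SIGNIFICANT_P,
    suggestive_p: float = SUGGESTIVE_P,
) -> pd.DataFrame:
    """Test every (phenotype, SNP) pair; one result row each.

    ``codes`` is indexed by sample (rows aligned with ``genotypes``)
    with one column per phenotype; ``variants`` aligns with genotype
    columns and provides snp_id/chrom/pos.
    """
    if len(codes) != genotypes.shape[0]:
        raise ValueError("codes rows must align with genotype rows")
    if len(variants) != genotypes.shape[1]:
        raise ValueError("variants must align with genotype columns")
    rows = []
    for pheno in codes.columns:
        y = codes[pheno].to_numpy(dtype=float)
        for j, var in enumerate(variants.itertuples(index=False)):
            r = wald_qtl(y, genotypes[:, j])
            tier = (assign_tier(r.wald_p, significant_p, suggestive_p)
                    if r.testable else "none")
            bonf = bonferroni_adjust(r.wald_p, m_tests) if r.testable else np.nan
            rows.append((pheno, var.chrom, var.pos, var.snp_id, r.beta, r.se,
                         r.wald_p, r.lrt_p, bonf, tier, r.n_used,
                         r.testable, r.degenerate))
    return pd.DataFrame(
        rows,
        columns=["phenotype", "chrom", "pos", "snp_id", "beta", "se",
                 "wald_p", "lrt_p", "bonferroni", "tier", "n_used",
                 "testable", "degenerate"],
    )


def cluster_loci(
    results: pd.DataFrame,
    window_bp: int = DEFAULT_CLUSTER_WINDOW,
    min_neighbors: int = 4,
) -> pd.DataFrame:
    """Group tiered SNPs into loci; label each singleton or clustered.

    Tiered SNPs (significant or suggestive) on the same chromosome are
    single-linkage connected when within ``window_bp``.  A connected
    group is *clustered* iff some member has at least ``min_neighbors``
    other members within ``window_bp`` of its own position ("more than
    three" co-segregating neighbors under the default); otherwise its
    members are reported as singletons that share a group annotation.
    Duplicate positions from multiple phenotypes count once.
    """
    tiered = results[results["tier"].isin(["significant", "suggestive"])]
    snps = (tiered[["snp_id", "chrom", "pos"]]
            .drop_duplicates("snp_id")
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True))
    out_rows = []
    locus_counter = 0
    for chrom, grp in snps.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        ids = grp["snp_id"].to_numpy()
        # single-linkage: a gap > window starts a new group
        breaks = np.flatnonzero(np.diff(pos) > window_bp)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for s, e in zip(starts, ends):
            locus_counter += 1
            p = pos[s:e + 1]
            n_neighbors = np.array(
                [np.sum(np.abs(p - x) <= window_bp) - 1 for x in p]
            )
            clustered = bool((n_neighbors >= min_neighbors).any())
            kind = "clustered" if clustered else "singleton"
            for i in range(s, e + 1):
                out_rows.append((ids[i], chrom, int(pos[i]),
                                 f"locus_{locus_counter}", kind,
                                 int(e - s + 1)))
    return pd.DataFrame(
        out_rows,
        columns=["snp_id", "chrom", "pos", "locus_id", "locus_kind", "locus_size"],
    )


def replication_select(
    combined: pd.DataFrame,
    pop1: pd.DataFrame,
    pop2: pd.DataFrame,
    *,
    combined_p_max: float = SUGGESTIVE_P,
    pop_p_max: float = 0.05,
) -> pd.DataFrame:
    """Replicated SNPs: combined p < 1e-5 and both population p < 0.05.

    Results are matched on (phenotype, snp_id); a key present in the
    combined table but absent from a population table is an error.
    Beta sign concordance across the three analyses is reported
    alongside (it does not gate selection).
    """
    keys = ["phenotype", "snp_id"]
    merged = combined.merge(
        pop1[keys + ["beta", "wald_p"]].rename(
            columns={"beta": "beta_pop1", "wald_p": "wald_p_pop1"}),
        on=keys, how="left", validate="1:1", indicator="_in1",
    ).merge(
        pop2[keys + ["beta", "wald_p"]].rename(
            columns={"beta": "beta_pop2", "wald_p": "wald_p_pop2"}),
        on=keys, how="left", validate="1:1", indicator="_in2",
    )
    absent = (merged["_in1"] != "both") | (merged["_in2"] != "both")
    if absent.any():
        raise ValueError(
            f"population results missing for keys:\n{merged.loc[absent, keys]}"
        )
    merged = merged.drop(columns=["_in1", "_in2"])
    merged["selected"] = (
        (merged["wald_p"] < combined_p_max)
        & (merged["wald_p_pop1"] < pop_p_max)
        & (merged["wald_p_pop2"] < pop_p_max)
    )
    signs = np.sign(merged[["beta", "beta_pop1", "beta_pop2"]].to_numpy())
    merged["sign_concordant"] = (signs == signs[:, [0]]).all(axis=1)
    return merged


def plot_manhattan(results: pd.DataFrame, path, *,
                   significant_p: float = SIGNIFICANT_P,
                   suggestive_p: float = SUGGESTIVE_P) -> None:
    """Plain Manhattan plot of -log10 Wald p by genome order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results.dropna(subset=["wald_p"]).sort_values(["chrom", "pos"])
    x = np.arange(len(df))
    y = -np.log10(df["wald_p"].to_numpy())
    fig, ax = plt.subplots(figsize=(9, 3))
    for i, (_, grp) in enumerate(df.groupby("chrom", sort=False)):
        idx = df.index.get_indexer(grp.index)
        ax.scatter(x[idx], y[idx], s=6, color="C0" if i % 2 == 0 else "C1")
    ax.axhline(-np.log10(significant_p), color="red", lw=0.8)
    ax.axhline(-np.log10(suggestive_p), color="gray", lw=0.8, ls="--")
    ax.set_xlabel("genome order")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_qq(results: pd.DataFrame, path) -> None:
    """Plain QQ plot of observed vs expected -log10 Wald p."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(results["wald_p"].dropna().to_numpy())
    n = len(p)
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)  # descending
    obs = -np.log10(p)  # p ascending -> obs descending, pairs with exp
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(exp, obs, s=6)
    lim = max(exp.max(), obs.max()) if n else 1.0
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
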