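import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from facegrowth import association as assoc
from facegrowth import simulate as sim


def ols_oracle(y, x):
    """Independent closed-form normal-equations least squares.

    Solves [n, Sx; Sx, Sxx] [a; b] = [Sy; Sxy] by explicit 2x2 inversion
    and derives the slope SE / t / p from first principles.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    Sx, Sy = x.sum(), y.sum()
    Sxx, Sxy = (x * x).sum(), (x * y).sum()
    det = n * Sxx - Sx * Sx
    a = (Sxx * Sy - Sx * Sxy) / det
    b = (n * Sxy - Sx * Sy) / det
    resid = y - a - b * x
    sigma2 = (resid @ resid) / (n - 2)
    se = math.sqrt(sigma2 * n / det)
    t = b / se
    p = 2 * sps.t.sf(abs(t), n - 2)
    return b, se, p


class TestWaldQtl:
    def test_matches_closed_form_oracle_on_fixture(self):
        # fixed 12-sample worked dataset
        dosages = np.array([0, 1, 2, 0, 1, 2, 0, 0, 1, 2, 1, 1])
        codes = np.array([1, 3, 4, 2, 2, 5, 1, 2, 3, 4, 3, 2])
        r = assoc.wald_qtl(codes, dosages)
        b, se, p = ols_oracle(codes, dosages)
        assert r.beta == pytest.approx(b, rel=1e-10)
        assert r.se == pytest.approx(se, rel=1e-10)
        assert r.wald_p == pytest.approx(p, rel=1e-10)
        assert r.n_used == 12

    def test_perfect_fit_flagged_degenerate(self):
        r = assoc.wald_qtl([1, 3, 5, 1, 3, 5], [0, 1, 2, 0, 1, 2])
        assert r.beta == pytest.approx(2.0)
        assert r.degenerate
        assert 0 < r.wald_p <= assoc.P_FLOOR

    def test_missing_dropped_pairwise(self):
        codes = np.array([1.0, 2, 3, 4, 5, np.nan])
        dosages = np.array([0, 1, 2, -1, 1, 2])
        r = assoc.wald_qtl(codes, dosages)
        assert r.n_used == 4

    def test_monomorphic_untestable(self):
        r = assoc.wald_qtl([1, 2, 3, 4], [1, 1, 1, 1])
        assert not r.testable and r.reason == "monomorphic"

    def test_constant_phenotype_untestable(self):
        r = assoc.wald_qtl([3, 3, 3, 3], [0, 1, 2, 1])
        assert not r.testable and r.reason == "constant_phenotype"

    def test_type_i_error_calibration(self):
        # permutation/simulation null at alpha=.05 and .01, 1000 SNPs, n=272
        n, n_snps = 272, 1000
        rng = np.random.default_rng(123)
        codes = rng.choice([1, 2, 3, 4, 5], size=n,
                           p=sim.DEFAULT_MARGINALS)
        rej05 = rej01 = 0
        for _ in range(n_snps):
            g = rng.binomial(2, 0.3, size=n)
            p = assoc.wald_qtl(codes, g).wald_p
            rej05 += p < 0.05
            rej01 += p < 0.01
        for alpha, rej in [(0.05, rej05), (0.01, rej01)]:
            se = math.sqrt(alpha * (1 - alpha) / n_snps)
            assert abs(rej / n_snps - alpha) < 3 * se


class TestLrtQtl:
    def test_no_improvement_gives_p_one(self):
        # orthogonal dosage: slope 0 exactly, RSS0 == RSS1
        codes = np.array([1.0, 2.0, 1.0, 2.0])
        dosages = np.array([0, 0, 2, 2])
        r = assoc.wald_qtl(codes, dosages)
        assert r.lrt_p == pytest.approx(1.0)

    def test_asymptotic_agreement_with_wald(self):
        n, n_snps = 272, 1000
        rng = np.random.default_rng(99)
        codes = rng.choice([1, 2, 3, 4, 5], size=n, p=sim.DEFAULT_MARGINALS)
        wald, lrt = [], []
        for _ in range(n_snps):
            g = rng.binomial(2, 0.3, size=n)
            r = assoc.wald_qtl(codes, g)
            wald.append(r.wald_p)
            lrt.append(r.lrt_p)
        rho = sps.spearmanr(wald, lrt).statistic
        assert rho > 0.99

    def test_perfect_fit_floored(self):
        r = assoc.wald_qtl([1, 3, 5, 1, 3, 5], [0, 1, 2, 0, 1, 2])
        assert r.lrt_p == assoc.P_FLOOR and r.degenerate


class TestBonferroni:
    @pytest.mark.parametrize("p,expected", [
        (1.9e-9, 1.5e-3),
        (7.3e-9, 5.8e-3),
        (3.1e-8, 2.5e-2),
    ])
    def test_worked_examples_2sf(self, p, expected):
        assert assoc.format_2sf(assoc.bonferroni_adjust(p, 800_000)) == pytest.approx(expected)

    def test_identity_point(self):
        assert assoc.bonferroni_adjust(1 / 800_000, 800_000) == pytest.approx(1.0)

    def test_uncapped(self):
        assert assoc.bonferroni_adjust(0.5, 800_000) == pytest.approx(4.0e5)

    def test_linear_in_p(self):
        rng = np.random.default_rng(1)
        for p in rng.uniform(1e-12, 1, 20):
            assert assoc.bonferroni_adjust(p, 12345) == pytest.approx(p * 12345, rel=1e-15)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            assoc.bonferroni_adjust(0.0)


class TestTiers:
    @pytest.mark.parametrize("p,tier", [
        (1.9e-9, "significant"),
        (4.999e-8, "significant"),
        (5e-8, "suggestive"),
        (9.99e-6, "suggestive"),
        (1e-5, "none"),
        (0.5, "none"),
    ])
    def test_boundaries(self, p, tier):
        assert assoc.assign_tier(p) == tier

    def test_partition(self):
        rng = np.random.default_rng(7)
        ps = np.r_[rng.uniform(1e-12, 1, 200), [5e-8, 1e-5, 1.0]]
        for p in ps:
            assert assoc.assign_tier(p) in ("significant", "suggestive", "none")


class TestExtras:
    def test_ordinal_logit_detects_planted_effect(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.4, 400)
        latent = 1.0 * g + rng.standard_normal(400)
        codes = 1 + np.searchsorted([-1.0, -0.2, 0.4, 1.2], latent)
        assert assoc.ordinal_qtl(codes, g) < 1e-4

    def test_plot_files_written(self, tmp_path):
        rng = np.random.default_rng(1)
        res = pd.DataFrame({
            "chrom": np.repeat(["chr1", "chr2"], 50),
            "pos": np.tile(np.arange(1, 51) * 1000, 2),
            "wald_p": rng.uniform(1e-9, 1, 100),
        })
        assoc.plot_manhattan(res, tmp_path / "mh.png")
        assoc.plot_qq(res, tmp_path / "qq.png")
        assert (tmp_path / "mh.png").stat().st_size > 0
        assert (tmp_path / "qq.png").stat().st_size > 0


class TestClusterLoci:
    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "wald_p"])
        df["tier"] = [assoc.assign_tier(p) for p in df["wald_p"]]
        return df

    def test_five_close_snps_clustered(self):
        rows = [(f"s{i}", "chr1", 10_000 + i * 1000, 1e-6) for i in range(5)]
        loci = assoc.cluster_loci(self._results(rows))
        assert (loci["locus_kind"] == "clustered").all()
        assert loci["locus_id"].nunique() == 1
        assert len(loci) == 5

    def test_isolated_snp_singleton(self):
        rows = [("lone", "chr2", 5_000_000, 1e-9)]
        loci = assoc.cluster_loci(self._results(rows))
        assert loci.iloc[0]["locus_kind"] == "singleton"

    def test_three_close_snps_are_singletons_with_group(self):
        # no member has > 3 neighbors, so not clustered
        rows = [(f"s{i}", "chr1", 10_000 + i * 1000, 1e-6) for i in range(3)]
        loci = assoc.cluster_loci(self._results(rows))
        assert (loci["locus_kind"] == "singleton").all()
        assert loci["locus_id"].nunique() == 1  # shared group annotation
        assert (loci["locus_size"] == 3).all()

    def test_partition_no_snp_in_two_loci(self):
        rng = np.random.default_rng(4)
        rows = [(f"s{i}", f"chr{rng.integers(1, 4)}", int(rng.integers(1, 10**7)), 1e-6)
                for i in range(40)]
        res = self._results(rows)
        loci = assoc.cluster_loci(res)
        assert loci["snp_id"].is_unique
        assert set(loci["snp_id"]) == set(res["snp_id"])

    def test_untier_snps_excluded(self):
        rows = [("a", "chr1", 100, 1e-6), ("b", "chr1", 200, 0.5)]
        loci = assoc.cluster_loci(self._results(rows))
        assert loci["snp_id"].tolist() == ["a"]


class TestReplicationSelect:
    def _df(self, p, beta=0.5, pheno="H1", snp="s1"):
        return pd.DataFrame({"phenotype": [pheno], "snp_id": [snp],
                             "beta": [beta], "wald_p": [p]})

    def test_all_bounds_met(self):
        out = assoc.replication_select(self._df(3e-6), self._df(0.01), self._df(0.04))
        assert bool(out["selected"].iloc[0])
        assert bool(out["sign_concordant"].iloc[0])

    def test_pop2_fails(self):
        out = assoc.replication_select(self._df(3e-6), self._df(0.01), self._df(0.06))
        assert not bool(out["selected"].iloc[0])

    def test_sign_discordance_reported_not_gating(self):
        out = assoc.replication_select(self._df(3e-6, beta=0.5),
                                       self._df(0.01, beta=0.4),
                                       self._df(0.04, beta=-0.4))
        assert bool(out["selected"].iloc[0])
        assert not bool(out["sign_concordant"].iloc[0])

    def test_key_mismatch_raises(self):
        with pytest.raises(ValueError, match="missing"):
            assoc.replication_select(self._df(3e-6), self._df(0.01),
                                     self._df(0.04, snp="other"))

    def test_planted_effect_power(self):
        # power simulation against the generating model at generator defaults
        maf, eff = 0.3, 1.0
        n1, n2 = 172, 100
        n_rep, selected = 100, 0
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            specs = [sim.SNPSpec("s1", "chr1", 100, maf, 0.0, eff)]
            g, v = sim.gen_genotypes(specs, n1 + n2, rng)
            codes = sim.gen_pattern_codes(g, v, ["H1"], {"H1": {"s1": eff}},
                                          None, rng)
            y = codes["H1"].to_numpy(float)

            def res(idx):
                r = assoc.wald_qtl(y[idx], g[idx, 0])
                return pd.DataFrame({"phenotype": ["H1"], "snp_id": ["s1"],
                                     "beta": [r.beta], "wald_p": [r.wald_p]})

            out = assoc.replication_select(res(slice(None)), res(slice(0, n1)),
                                           res(slice(n1, n1 + n2)))
            selected += bool(out["selected"].iloc[0])
        assert selected / n_rep >= 0.8
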