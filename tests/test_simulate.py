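import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from facegrowth import genotype_qc as gqc
from facegrowth import simulate as sim
from facegrowth import trajectories as traj


class TestSpecs:
    def test_bad_maf_rejected(self):
        with pytest.raises(ValueError, match="maf"):
            sim.SNPSpec("s", "chr1", 1, maf=0.6)

    def test_bad_missing_rate_rejected(self):
        with pytest.raises(ValueError):
            sim.SNPSpec("s", "chr1", 1, maf=0.1, missing_rate=1.0)

    def test_bad_pos_rejected(self):
        with pytest.raises(ValueError):
            sim.SNPSpec("s", "chr1", 0, maf=0.1)

    def test_cohort_spec_bounds(self):
        with pytest.raises(ValueError):
            sim.CohortSpec(n_individuals=0)
        with pytest.raises(ValueError):
            sim.CohortSpec(photos_per_person_range=(2, 5))
        with pytest.raises(ValueError):
            sim.CohortSpec(noise_sd=-0.1)


class TestGenGenotypes:
    def test_zero_maf_all_zero(self):
        geno, _ = sim.gen_genotypes([sim.SNPSpec("s", "chr1", 1, 0.0)], 100, seed=0)
        assert (geno == 0).all()
        assert gqc.variant_stats(geno[:, 0]).maf == 0.0

    def test_determinism(self):
        specs = [sim.SNPSpec(f"s{j}", "chr1", j + 1, 0.2, missing_rate=0.1)
                 for j in range(10)]
        g1, v1 = sim.gen_genotypes(specs, 50, seed=42)
        g2, v2 = sim.gen_genotypes(specs, 50, seed=42)
        np.testing.assert_array_equal(g1, g2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            sim.gen_genotypes([sim.SNPSpec("s", "chr1", 1, 0.1)], 0, seed=0)

    def test_empirical_maf_within_3se(self):
        n, maf = 5000, 0.3
        geno, _ = sim.gen_genotypes([sim.SNPSpec("s", "chr1", 1, maf)], n, seed=1)
        est = gqc.variant_stats(geno[:, 0]).maf
        se = math.sqrt(maf * (1 - maf) / (2 * n))
        assert abs(est - maf) < 3 * se

    def test_hwe_rejection_rate_near_nominal(self):
        # 200 null SNPs: exact-test rejection at alpha=.05 within 3 MC SE
        n_snps, n = 200, 500
        specs = [sim.SNPSpec(f"s{j}", "chr1", j + 1, 0.3) for j in range(n_snps)]
        geno, _ = sim.gen_genotypes(specs, n, seed=3)
        rej = sum(gqc.variant_stats(geno[:, j]).hwe_p < 0.05 for j in range(n_snps))
        se = math.sqrt(0.05 * 0.95 / n_snps)
        assert abs(rej / n_snps - 0.05) <= 3 * se

    def test_missingness_rate(self):
        geno, _ = sim.gen_genotypes(
            [sim.SNPSpec("s", "chr1", 1, 0.3, missing_rate=0.2)], 5000, seed=2)
        frac = (geno == gqc.MISSING).mean()
        assert abs(frac - 0.2) < 3 * math.sqrt(0.2 * 0.8 / 5000)


class TestGenPatternCodes:
    def test_null_marginals_uniform_cutpoints(self):
        specs = [sim.SNPSpec("s", "chr1", 1, 0.3)]
        geno, variants = sim.gen_genotypes(specs, 20_000, seed=0)
        codes = sim.gen_pattern_codes(geno, variants, ["P"],
                                      marginals=(0.2, 0.2, 0.2, 0.2, 0.2), seed=0)
        freqs = codes["P"].value_counts(normalize=True).sort_index()
        se = math.sqrt(0.2 * 0.8 / 20_000)
        assert freqs.index.tolist() == [1, 2, 3, 4, 5]
        assert (abs(freqs - 0.2) < 4 * se).all()

    def test_mean_code_monotone_in_dosage(self):
        specs = [sim.SNPSpec("s", "chr1", 1, 0.4, effect=2.0)]
        geno, variants = sim.gen_genotypes(specs, 5000, seed=1)
        codes = sim.gen_pattern_codes(geno, variants, ["P"],
                                      {"P": {"s": 2.0}}, seed=1)
        means = [codes["P"][geno[:, 0] == d].mean() for d in (0, 1, 2)]
        assert means[0] < means[1] < means[2]

    def test_unknown_snp_in_effects_rejected(self):
        specs = [sim.SNPSpec("s", "chr1", 1, 0.3)]
        geno, variants = sim.gen_genotypes(specs, 10, seed=0)
        with pytest.raises(KeyError, match="ghost"):
            sim.gen_pattern_codes(geno, variants, ["P"], {"P": {"ghost": 1.0}})

    def test_determinism(self):
        specs = [sim.SNPSpec("s", "chr1", 1, 0.3, effect=0.5)]
        geno, variants = sim.gen_genotypes(specs, 100, seed=5)
        c1 = sim.gen_pattern_codes(geno, variants, ["A", "B"], {"A": {"s": 0.5}}, seed=9)
        c2 = sim.gen_pattern_codes(geno, variants, ["A", "B"], {"A": {"s": 0.5}}, seed=9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_effect_recovery_ci_coverage(self):
        # downstream Wald CI covers the generative-model slope >= 90/100
        from facegrowth import association as assoc

        maf, eff, n = 0.3, 0.5, 2000
        true_slope = sim.expected_code_slope(maf, eff)
        covered = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            specs = [sim.SNPSpec("s1", "chr1", 100, maf, 0.0, eff)]
            g, v = sim.gen_genotypes(specs, n, rng)
            codes = sim.gen_pattern_codes(g, v, ["P"], {"P": {"s1": eff}}, None, rng)
            r = assoc.wald_qtl(codes["P"], g[:, 0])
            tcrit = sps.t.ppf(0.975, r.n_used - 2)
            covered += (r.beta - tcrit * r.se <= true_slope <= r.beta + tcrit * r.se)
        assert covered >= 90


class TestExpectedCodeSlope:
    def test_zero_effect_zero_slope(self):
        assert sim.expected_code_slope(0.3, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_numeric_integration(self):
        # independent oracle: Monte-Carlo integration of the latent model
        rng = np.random.default_rng(0)
        maf, eff = 0.25, 0.6
        g = rng.binomial(2, maf, size=400_000)
        latent = eff * g + rng.standard_normal(g.size)
        cuts = sim.pattern_cutpoints(sim.DEFAULT_MARGINALS)
        code = 1 + np.searchsorted(cuts, latent)
        slope = np.polyfit(g, code, 1)[0]
        assert sim.expected_code_slope(maf, eff) == pytest.approx(slope, abs=0.01)


class TestGenTrajectories:
    def _codes(self, codes, pheno="H1"):
        return pd.DataFrame({pheno: codes})

    def test_cc_noise_free_constant(self):
        spec = sim.CohortSpec(n_individuals=1, noise_sd=0.0, seed=0)
        df = sim.gen_trajectories(self._codes([3]), spec,
                                  base_sd=0.0, amplitude_sd=0.0)
        assert df["value"].nunique() == 1

    def test_dd_noise_free_decreasing(self):
        spec = sim.CohortSpec(n_individuals=1, noise_sd=0.0, seed=1)
        df = sim.gen_trajectories(self._codes([1]), spec,
                                  base_sd=0.0, amplitude_sd=0.0).sort_values("age")
        assert (np.diff(df["value"]) < 0).all()

    def test_relative_age_span(self):
        spec = sim.CohortSpec(n_individuals=5, noise_sd=0.0, seed=2)
        df = sim.gen_trajectories(self._codes([5] * 5), spec)
        rel = df["age"] - df["current_age"]
        assert rel.max() == 0.0
        assert (rel >= -df["current_age"]).all()
        per_person = df.groupby("person_id")["photo_id"].nunique()
        assert per_person.between(6, 8).all()  # 5-7 past + current

    def test_invalid_code_rejected(self):
        spec = sim.CohortSpec(n_individuals=1, seed=0)
        with pytest.raises(ValueError, match="code"):
            sim.gen_trajectories(self._codes([6]), spec)

    def test_round_trip_noise_free_all_codes(self):
        spec = sim.CohortSpec(n_individuals=10, noise_sd=0.0, seed=4)
        codes = pd.DataFrame({"H1": [1, 2, 3, 4, 5] * 2})
        df = sim.gen_trajectories(codes, spec)
        trajs, unc = traj.build_trajectories(df)
        assert len(unc) == 0
        cls = traj.classify_cohort(trajs).sort_values("person_id")
        assert cls["code"].tolist() == codes["H1"].tolist()

    def test_determinism(self):
        spec = sim.CohortSpec(n_individuals=3, noise_sd=0.05, seed=8)
        codes = self._codes([1, 3, 5])
        d1 = sim.gen_trajectories(codes, spec)
        d2 = sim.gen_trajectories(codes, spec)
        pd.testing.assert_frame_equal(d1, d2)


class TestLandmarkFixtures:
    def test_ground_truth_matches_compute(self, landmark_fixture):
        from facegrowth import landmarks as lmk

        lm_df, truth = landmark_fixture
        table = lmk.MeasurementTable.default()
        for _, row in lm_df.iterrows():
            rec = lmk._parse_row(row.astype(str).to_dict())
            got = lmk.compute_phenotypes(rec, table).values
            want = truth[truth.photo_id == rec.photo_id].set_index("phenotype")["value"]
            for name, v in got.items():
                assert v == pytest.approx(want[name], rel=1e-12)

    def test_iris_pair_truth_is_one(self):
        from facegrowth import landmarks as lmk

        table = lmk.MeasurementTable(
            [lmk.Measurement("IOD", lmk.IRIS_LEFT, lmk.IRIS_RIGHT, "horizontal")]
        )
        _, truth = sim.gen_landmark_fixtures(2, seed=1, table=table)
        assert (truth["value"] == pytest.approx(1.0)).all() or \
            np.allclose(truth["value"], 1.0, rtol=1e-12)

    def test_scale_invariance_of_truth(self):
        lm1, t1 = sim.gen_landmark_fixtures(2, seed=77)
        lm2, t2 = sim.gen_landmark_fixtures(2, seed=77)
        coord_cols = [c for c in lm2.columns if c.endswith(("_x", "_y"))]
        lm2[coord_cols] = lm2[coord_cols] * 7.0
        # recompute truth by the same arithmetic on scaled coordinates
        from facegrowth import landmarks as lmk
        table = lmk.MeasurementTable.default()
        for (_, row), (_, want) in zip(lm2.iterrows(),
                                       t1.groupby("photo_id", sort=False)):
            rec = lmk._parse_row(row.astype(str).to_dict())
            got = lmk.compute_phenotypes(rec, table).values
            w = want.set_index("phenotype")["value"]
            for name, v in got.items():
                assert v == pytest.approx(w[name], rel=1e-12)

    def test_zero_photos_rejected(self):
        with pytest.raises(ValueError):
            sim.gen_landmark_fixtures(0)


class TestComponentRng:
    def test_streams_differ_and_reproduce(self):
        a1 = sim.component_rng(1, "x").random(5)
        a2 = sim.component_rng(1, "x").random(5)
        b = sim.component_rng(1, "y").random(5)
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(a1, b)
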