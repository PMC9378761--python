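import numpy as np
import pandas as pd
import pytest

from facegrowth import landmarks as lmk
from facegrowth import simulate as sim


@pytest.fixture
def default_table():
    return lmk.MeasurementTable.default()


@pytest.fixture
def landmark_fixture():
    """Three random landmark records + independently computed ground truth."""
    return sim.gen_landmark_fixtures(3, seed=42)


@pytest.fixture
def landmark_csv(tmp_path, landmark_fixture):
    lm_df, truth = landmark_fixture
    path = tmp_path / "landmarks.csv"
    sim.write_landmark_csv(lm_df, path)
    return path


def make_phenotype_df(codes_by_person, phenotype="H1", current_age=19,
                      ages=(5, 9, 13, 16, 19), noise_sd=0.0, seed=0):
    """Small noise-controlled trajectory table for classifier tests."""
    spec = sim.CohortSpec(n_individuals=len(codes_by_person), noise_sd=noise_sd,
                          current_age_range=(current_age, current_age), seed=seed)
    rng = np.random.default_rng(seed)
    codes = pd.DataFrame({phenotype: list(codes_by_person)})
    df = sim.gen_trajectories(codes, spec, rng=rng)
    return df


@pytest.fixture
def small_cohort():
    """172+100-person synthetic cohort pieces used by integration tests."""
    specs = [sim.SNPSpec(f"S{j}", "chr1", 1000 + j * 10**6, 0.3) for j in range(5)]
    geno, variants = sim.gen_genotypes(specs, 272, seed=7)
    codes = sim.gen_pattern_codes(geno, variants, ["H1", "V1"], seed=7)
    return geno, variants, codes
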