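"""Synthetic cohorts with the statistical structure the pipeline assumes.

Genotypes are drawn in Hardy-Weinberg equilibrium (two independent
allele draws per sample), per-phenotype growth-pattern codes come from
a latent-propensity threshold model with optional planted SNP effects,
and trajectories are quadratic templates realizing each coded pattern
plus Gaussian noise.  Everything is reproducible from a single integer
seed; independent substreams are derived per component so modules can
be exercised in isolation.

Writers emit the pipeline's text input formats: landmark CSV, VCF,
PLINK-style .ped/.map and a ground-truth TSV for tests.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import landmarks as lmk
from .genotype_qc import MISSING
from .trajectories import CODE_TO_LABEL

__all__ = [
    "SNPSpec",
    "CohortSpec",
    "DEFAULT_MARGINALS",
    "gen_genotypes",
    "pattern_cutpoints",
    "gen_pattern_codes",
    "expected_code_slope",
    "default_marginals_for",
    "true_patterns_frame",
    "gen_trajectories",
    "gen_landmark_fixtures",
    "write_landmark_csv",
    "write_vcf",
    "write_ped_map",
    "component_rng",
]

#: Default marginal pattern frequencies for codes 1..5.  Pattern 5
#: (continued increase) dominates most measurements; eye-region
#: phenotypes instead lean to pattern 1 (see EYE_MARGINALS).
DEFAULT_MARGINALS = (0.1, 0.1, 0.1, 0.1, 0.6)
EYE_MARGINALS = (0.6, 0.1, 0.1, 0.1, 0.1)


@dataclass(frozen=True)
class SNPSpec:
    """Generative description of one biallelic SNP."""

    snp_id: str
    chrom: str
    pos: int
    maf: float
    missing_rate: float = 0.0
    effect: float = 0.0  # per-allele shift on the latent pattern propensity

    def __post_init__(self):
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must be in [0, 0.5], got {self.maf}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"{self.snp_id}: missing_rate must be in [0, 1)")
        if self.pos <= 0:
            raise ValueError(f"{self.snp_id}: pos must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort shape parameters (defaults mirror the larger study group)."""

    n_individuals: int = 172
    current_age_range: tuple[int, int] = (18, 20)
    photos_per_person_range: tuple[int, int] = (5, 7)  # past photos
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.photos_per_person_range[0] < 3:
            raise ValueError("need at least 3 past photos for fitting")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Derive a named, independent random stream from the global seed."""
    # zlib.crc32 is stable across processes (str.hash is salted)
    key = zlib.crc32(component.encode())
    child = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return np.random.default_rng(child)


def default_marginals_for(phenotype: str) -> tuple[float, ...]:
    """Default pattern marginals: eye-width phenotypes lean to pattern 1,
    everything else to pattern 5."""
    return EYE_MARGINALS if phenotype in ("H1", "H2", "H7", "H8") else DEFAULT_MARGINALS


def gen_genotypes(
    snp_specs: list[SNPSpec], n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw an n x m dosage matrix under HWE with per-SNP missingness.

    Each dosage is the sum of two independent Bernoulli(maf) allele
    draws, so genotype frequencies are Hardy-Weinberg in expectation.
    Missing entries are set to -1 with probability ``missing_rate``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else component_rng(seed, "genotypes"))
    m = len(snp_specs)
    geno = np.empty((n, m), dtype=np.int8)
    for j, spec in enumerate(snp_specs):
        alleles = rng.random((n, 2)) < spec.maf
        geno[:, j] = alleles.sum(axis=1)
        if spec.missing_rate > 0:
            geno[rng.random(n) < spec.missing_rate, j] = MISSING
    variants = pd.DataFrame(
        [(s.snp_id, s.chrom, s.pos, "A", "G", s.maf, s.missing_rate, s.effect)
         for s in snp_specs],
        columns=["snp_id", "chrom", "pos", "ref", "alt",
                 "true_maf", "missing_rate", "effect"],
    )
    return geno, variants


def pattern_cutpoints(marginals=DEFAULT_MARGINALS) -> np.ndarray:
    """Latent-scale thresholds giving the requested null marginals.

    Cut points are standard-normal quantiles of the cumulative marginal
    frequencies, exact when all SNP effects are zero and approximate
    (slightly attenuated marginals) otherwise.
    """
    marginals = np.asarray(marginals, dtype=float)
    if marginals.shape != (5,) or (marginals <= 0).any():
        raise ValueError("marginals must be 5 positive frequencies")
    if not math.isclose(marginals.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("marginals must sum to 1")
    return norm.ppf(np.cumsum(marginals)[:4])


def gen_pattern_codes(
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    phenotype_names: list[str],
    causal_effects: dict[str, dict[str, float]] | None = None,
    marginals=None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-individual, per-phenotype ordinal codes 1..5.

    For each phenotype the latent propensity is
    ``sum_j effect_j * dosage_j + N(0, 1)`` (missing dosages imputed at
    the SNP's called mean, for generation only), discretized at fixed
    cut points.  ``causal_effects`` maps phenotype -> {snp_id: effect};
    phenotypes absent from it are pure null.  ``marginals`` may be one
    5-vector for all phenotypes or a mapping phenotype -> 5-vector.
    """
    n = genotypes.shape[0]
    rng = (seed if isinstance(seed, np.random.Generator)
           else component_rng(seed, "pattern_codes"))
    causal_effects = causal_effects or {}
    snp_index = {s: j for j, s in enumerate(variants["snp_id"])}
    for pheno, effs in causal_effects.items():
        unknown = [s for s in effs if s not in snp_index]
        if unknown:
            raise KeyError(f"{pheno}: unknown SNP id(s) in effects: {unknown}")

    codes = {}
    for pheno in phenotype_names:
        shift = np.zeros(n)
        for snp_id, eff in causal_effects.get(pheno, {}).items():
            d = genotypes[:, snp_index[snp_id]].astype(float)
            miss = d == MISSING
            if miss.all():
                raise ValueError(f"{snp_id}: all dosages missing")
            d[miss] = d[~miss].mean()
            shift += eff * d
        latent = shift + rng.standard_normal(n)
        marg = (marginals.get(pheno, DEFAULT_MARGINALS)
                if isinstance(marginals, dict)
                else (DEFAULT_MARGINALS if marginals is None else marginals))
        cuts = pattern_cutpoints(marg)
        codes[pheno] = 1 + np.searchsorted(cuts, latent)
    return pd.DataFrame(codes, index=pd.RangeIndex(n, name="individual"))


def expected_code_slope(maf: float, effect: float, marginals=DEFAULT_MARGINALS) -> float:
    """Population OLS slope of code on dosage under the generative model.

    Independent oracle for parameter-recovery tests: with latent
    ``effect * g + N(0, 1)`` and fixed cut points ``c_k``,
    ``E[code | g] = 1 + sum_k P(latent > c_k)`` and the least-squares
    slope is Cov(g, E[code | g]) / Var(g) with g ~ HWE(maf).
    """
    cuts = pattern_cutpoints(marginals)
    g = np.array([0.0, 1.0, 2.0])
    w = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    ey = 1.0 + norm.sf(cuts[None, :] - effect * g[:, None]).sum(axis=1)
    mg = float(w @ g)
    return float(w @ ((g - mg) * ey)) / float(w @ (g - mg) ** 2)


# ---------------------------------------------------------------------------
# trajectory templates

#: Turning point of the DI/ID parabolas, as a fraction of the age span
#: measured back from the current photo.  Off-center (toward the current
#: photo) so DI has a net *decrease* and ID a net *increase*, keeping the
#: mean fitted total change strictly ordered across codes 1 < 2 < 3 < 4 < 5.
VERTEX_FRAC = 0.3


def _template_value(code: int, t: float, span: float, base: float, amp: float) -> float:
    """Noise-free trajectory value at relative age t in [-span, 0]."""
    if code == 1:    # continued decrease
        return base - amp * (t + span) / span
    if code == 2:    # decrease then increase (valley at -VERTEX_FRAC*span)
        u = (t + VERTEX_FRAC * span) / ((1.0 - VERTEX_FRAC) * span)
        return base + amp * u * u
    if code == 3:    # constant
        return base
    if code == 4:    # increase then decrease (mirror of DI)
        u = (t + VERTEX_FRAC * span) / ((1.0 - VERTEX_FRAC) * span)
        return base - amp * u * u
    if code == 5:    # continued increase
        return base + amp * (t + span) / span
    raise ValueError(f"invalid pattern code {code}")


def gen_trajectories(
    codes: pd.DataFrame,
    cohort_spec: CohortSpec,
    *,
    base: float = 1.0,
    amplitude: float = 0.3,
    base_sd: float = 0.1,
    amplitude_sd: float = 0.05,
    cohort_label: str = "POP",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Measurement series realizing each person's coded patterns.

    One set of photo ages per person (shared by all phenotypes, as each
    photo yields all measurements): 5-7 distinct past ages plus the
    current photo at relative age 0.  Values follow the pattern template
    plus N(0, noise_sd) noise.  Baseline level and pattern amplitude
    vary per (person, phenotype) with sds ``base_sd``/``amplitude_sd``
    so the pooled value distribution is continuous rather than a few
    point masses (keeps tail trimming from hitting one age group only).
    Returns the long-format phenotype table consumed by the pipeline.
    """
    bad = set(np.unique(codes.to_numpy())) - {1, 2, 3, 4, 5}
    if bad:
        raise ValueError(f"invalid pattern code(s) {sorted(bad)}")
    if rng is None:
        rng = component_rng(cohort_spec.seed, "trajectories")

    recs = []
    for i, (_, person_codes) in enumerate(codes.iterrows()):
        person = f"{cohort_label}_{i:04d}"
        current_age = int(rng.integers(cohort_spec.current_age_range[0],
                                       cohort_spec.current_age_range[1] + 1))
        n_past = int(rng.integers(cohort_spec.photos_per_person_range[0],
                                  cohort_spec.photos_per_person_range[1] + 1))
        # the earliest photo is always at age 2 so the DI/ID turning point
        # is guaranteed to fall inside the observed span
        later = rng.choice(np.arange(3, current_age), size=n_past - 1, replace=False)
        ages = np.sort(np.r_[2, later, current_age])
        bases = {p: base + rng.normal(0.0, base_sd) for p in person_codes.index}
        amps = {p: max(amplitude + rng.normal(0.0, amplitude_sd), 0.05)
                for p in person_codes.index}
        for k, age in enumerate(ages):
            photo = f"{person}_p{k}"
            t = float(age - current_age)
            for pheno, code in person_codes.items():
                value = _template_value(int(code), t, float(current_age),
                                        bases[pheno], amps[pheno])
                value += rng.normal(0.0, cohort_spec.noise_sd)
                recs.append((person, photo, float(age), float(current_age), pheno, value))
    return pd.DataFrame(
        recs, columns=["person_id", "photo_id", "age", "current_age", "phenotype", "value"]
    )


def true_patterns_frame(codes: pd.DataFrame, cohort_label: str = "POP") -> pd.DataFrame:
    """Ground-truth long table (person_id, phenotype, code, label) for tests."""
    rows = []
    for i, (_, person_codes) in enumerate(codes.iterrows()):
        person = f"{cohort_label}_{i:04d}"
        for pheno, code in person_codes.items():
            rows.append((person, pheno, int(code), CODE_TO_LABEL[int(code)]))
    return pd.DataFrame(rows, columns=["person_id", "phenotype", "code", "label"])


# ---------------------------------------------------------------------------
# landmark fixtures

#: Canonical face layout (interocular distance 60 units) used as the
#: jitter base for fixtures; coordinates are pixel-like, y grows down.
_BASE_FACE: dict[str, tuple[float, float]] = {
    "iris_L": (-30.0, 0.0), "iris_R": (30.0, 0.0),
    "en_l": (-12.0, 0.0), "en_r": (12.0, 0.0),
    "ex_l": (-45.0, 0.0), "ex_r": (45.0, 0.0),
    "n": (0.0, -12.0),
    "prn": (0.0, 28.0),
    "sn": (0.0, 38.0),
    "al_l": (-14.0, 32.0), "al_r": (14.0, 32.0),
    "ch_l": (-22.0, 60.0), "ch_r": (22.0, 60.0),
    "ls": (0.0, 54.0),
    "sto": (0.0, 62.0),
    "li": (0.0, 70.0),
    "gn": (0.0, 95.0),
    "zy_l": (-55.0, 25.0), "zy_r": (55.0, 25.0),
    "go_l": (-42.0, 70.0), "go_r": (42.0, 70.0),
}


def gen_landmark_fixtures(
    n_photos: int,
    seed: int | np.random.Generator = 0,
    *,
    jitter: float = 2.0,
    table: "lmk.MeasurementTable | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random landmark records plus independently computed ground truth.

    Returns (landmark table in the CSV column layout, long ground-truth
    table of normalized distances).  The ground truth is computed with
    plain coordinate arithmetic, independent of the phenotyping code
    path, so the two can be compared in tests.
    """
    if n_photos < 1:
        raise ValueError("n_photos must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else component_rng(seed, "landmark_fixtures"))
    if table is None:
        table = lmk.MeasurementTable.default()

    lm_rows, truth_rows = [], []
    for i in range(n_photos):
        scale = float(rng.uniform(0.5, 3.0))
        theta = float(rng.uniform(0, 2 * math.pi))
        shift = rng.uniform(-100, 100, size=2)
        cos_t, sin_t = math.cos(theta), math.sin(theta)

        pts = {}
        for name, (x0, y0) in _BASE_FACE.items():
            jx, jy = rng.normal(0.0, jitter, size=2)
            x, y = x0 + jx, y0 + jy
            pts[name] = (scale * (cos_t * x - sin_t * y) + shift[0],
                         scale * (sin_t * x + cos_t * y) + shift[1])

        person, photo = f"FIX_{i:03d}", f"FIX_{i:03d}_p0"
        age, current_age = 19.0, 19.0
        row = {"person_id": person, "photo_id": photo,
               "age": age, "current_age": current_age,
               "iris_L_x": pts["iris_L"][0], "iris_L_y": pts["iris_L"][1],
               "iris_R_x": pts["iris_R"][0], "iris_R_y": pts["iris_R"][1]}
        for name in lmk.LANDMARK_NAMES:
            row[f"{name}_x"], row[f"{name}_y"] = pts[name]
        lm_rows.append(row)

        # ground truth by direct arithmetic (independent code path)
        iod = math.hypot(pts["iris_L"][0] - pts["iris_R"][0],
                         pts["iris_L"][1] - pts["iris_R"][1])
        for entry in table:
            ax, ay = pts[entry.point_a]
            bx, by = pts[entry.point_b]
            truth_rows.append(
                (person, photo, entry.name, math.hypot(ax - bx, ay - by) / iod)
            )

    lm_df = pd.DataFrame(lm_rows, columns=lmk.LANDMARK_CSV_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["person_id", "photo_id", "phenotype", "value"])
    return lm_df, truth


# ---------------------------------------------------------------------------
# writers (text formats only)

def write_landmark_csv(lm_df: pd.DataFrame, path) -> None:
    lm_df.to_csv(path, index=False)


def write_vcf(genotypes: np.ndarray, variants: pd.DataFrame,
              sample_ids: list[str], path) -> None:
    """Write dosages as a minimal plain-text VCF (GT only, '.' missing)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(variants["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        order = variants.reset_index(drop=True)
        for j in order.sort_values(["chrom", "pos"]).index:
            var = order.loc[j]
            gts = "\t".join(gt_map[int(g)] for g in genotypes[:, j])
            fh.write(f"{var['chrom']}\t{var['pos']}\t{var['snp_id']}\t"
                     f"{var['ref']}\t{var['alt']}\t.\t.\t.\tGT\t{gts}\n")


def write_ped_map(genotypes: np.ndarray, variants: pd.DataFrame,
                  sample_ids: list[str], ped_path, map_path) -> None:
    """Write PLINK-style text .ped/.map (allele codes from ref/alt)."""
    with open(map_path, "w") as fh:
        for var in variants.itertuples(index=False):
            fh.write(f"{var.chrom}\t{var.snp_id}\t0\t{var.pos}\n")
    ref = variants["ref"].to_numpy()
    alt = variants["alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(genotypes.shape[1]):
                g = int(genotypes[i, j])
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [alt[j] if g >= 1 else ref[j],
                               alt[j] if g == 2 else ref[j]]
            fh.write(" ".join(fields) + "\n")
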