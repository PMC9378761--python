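"""Pipeline configuration: defaults, YAML round-trip, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .association import DEFAULT_CLUSTER_WINDOW, DEFAULT_M_TESTS, SIGNIFICANT_P, SUGGESTIVE_P
from .genotype_qc import DEFAULT_CALL_RATE_MIN, DEFAULT_HWE_P_MIN, DEFAULT_MAF_MIN

__all__ = ["PipelineConfig", "validate_config", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # synthetic cohorts (used when landmarks_path/phenotypes_path are unset)
    seed: int = 0
    n_pop1: int = 172
    n_pop2: int = 100
    n_snps: int = 200
    n_causal: int = 3
    causal_effect: float = 1.0
    noise_sd: float = 0.02
    current_age_range: tuple[int, int] = (18, 20)
    photos_per_person_range: tuple[int, int] = (5, 7)
    # optional real inputs
    landmarks_path: str | None = None
    vcf_path: str | None = None
    # measurement table: None = default 10 H + 11 V pairs
    measurement_table: list[dict] | None = None
    # measurement QC
    trim_pct: float = 2.0
    trim_method: str = "percentile"
    # classifier
    eps_rel: float = 0.02
    fit_degree: int = 2
    min_obs: int = 3
    # genotype QC
    call_rate_min: float = DEFAULT_CALL_RATE_MIN
    maf_min: float = DEFAULT_MAF_MIN
    hwe_p_min: float = DEFAULT_HWE_P_MIN
    # association
    m_tests: int = DEFAULT_M_TESTS
    significant_p: float = SIGNIFICANT_P
    suggestive_p: float = SUGGESTIVE_P
    cluster_window: int = DEFAULT_CLUSTER_WINDOW
    replication_pop_p: float = 0.05
    # output
    out_dir: str = "facegrowth_out"
    make_plots: bool = False

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["current_age_range"] = list(d["current_age_range"])
        d["photos_per_person_range"] = list(d["photos_per_person_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for k in ("current_age_range", "photos_per_person_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def validate_config(config: PipelineConfig) -> list[str]:
    """Total validation; returns a list of violation messages (empty = ok)."""
    v: list[str] = []

    def bound(name, value, lo=None, hi=None, lo_strict=False, hi_strict=False):
        if lo is not None and (value <= lo if lo_strict else value < lo):
            v.append(f"{name}={value} below bound {lo}")
        elif hi is not None and (value >= hi if hi_strict else value > hi):
            v.append(f"{name}={value} above bound {hi}")

    bound("n_pop1", config.n_pop1, lo=1)
    bound("n_pop2", config.n_pop2, lo=1)
    bound("n_snps", config.n_snps, lo=1)
    bound("n_causal", config.n_causal, lo=0, hi=config.n_snps)
    bound("noise_sd", config.noise_sd, lo=0)
    bound("trim_pct", config.trim_pct, lo=0, hi=50, hi_strict=True)
    if config.trim_method not in ("percentile", "iqr"):
        v.append(f"trim_method={config.trim_method!r} not in (percentile, iqr)")
    bound("eps_rel", config.eps_rel, lo=0)
    if config.fit_degree not in (1, 2):
        v.append(f"fit_degree={config.fit_degree} not in (1, 2)")
    bound("min_obs", config.min_obs, lo=3)
    bound("call_rate_min", config.call_rate_min, lo=0, hi=1)
    bound("maf_min", config.maf_min, lo=0, hi=0.5)
    bound("hwe_p_min", config.hwe_p_min, lo=0, hi=1)
    bound("m_tests", config.m_tests, lo=1)
    bound("significant_p", config.significant_p, lo=0, hi=1, lo_strict=True)
    bound("suggestive_p", config.suggestive_p, lo=0, hi=1, lo_strict=True)
    if config.significant_p > config.suggestive_p:
        v.append(
            f"tier thresholds reversed: significant_p={config.significant_p} "
            f"> suggestive_p={config.suggestive_p}"
        )
    bound("cluster_window", config.cluster_window, lo=0)
    bound("replication_pop_p", config.replication_pop_p, lo=0, hi=1, lo_strict=True)
    lo_age, hi_age = config.current_age_range
    if not (0 < lo_age <= hi_age):
        v.append(f"current_age_range={config.current_age_range} invalid")
    lo_ph, hi_ph = config.photos_per_person_range
    if not (3 <= lo_ph <= hi_ph):
        v.append(f"photos_per_person_range={config.photos_per_person_range} invalid (min 3)")
    return v
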