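"""End-to-end orchestration with flat-file handoffs and a run manifest.

Stage order: generate (or ingest) -> phenotype -> measurement QC ->
classify -> genotype QC -> association (combined + per cohort) ->
replication.  Every stage writes its output as TSV into the run
directory so stages are independently inspectable, and a manifest
records the config hash, seed, versions and row counts; identical
config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc
from . import genotype_qc as gqc
from . import landmarks as lmk
from . import measurement_qc as mqc
from . import replication as repl
from . import simulate as sim
from . import trajectories as traj
from .config import PipelineConfig, validate_config

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("facegrowth")


class PipelineError(RuntimeError):
    """A stage failed; the failing stage is named in the message."""


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def _make_snp_panel(config: PipelineConfig) -> list[sim.SNPSpec]:
    rng = sim.component_rng(config.seed, "snp_panel")
    specs = []
    for j in range(config.n_snps):
        chrom = f"chr{1 + j % 22}"
        pos = 1_000_000 + 2_000_000 * (j // 22)
        maf = float(np.round(rng.uniform(0.10, 0.50), 3))
        specs.append(sim.SNPSpec(f"SNP_{j:05d}", chrom, pos, maf,
                                 missing_rate=0.005))
    return specs


def _plant_effects(config: PipelineConfig, specs: list[sim.SNPSpec],
                   phenotype_names: list[str]) -> dict[str, dict[str, float]]:
    """Assign each causal SNP a distinct phenotype, deterministically."""
    rng = sim.component_rng(config.seed, "causal_effects")
    if config.n_causal == 0:
        return {}
    snp_idx = rng.choice(len(specs), size=config.n_causal, replace=False)
    phenos = rng.choice(phenotype_names, size=config.n_causal,
                       replace=config.n_causal > len(phenotype_names))
    effects: dict[str, dict[str, float]] = {}
    for k, j in enumerate(snp_idx):
        effects.setdefault(str(phenos[k]), {})[specs[j].snp_id] = config.causal_effect
    return effects


def _codes_matrix(classified: pd.DataFrame, person_ids: list[str],
                  phenotypes: list[str]) -> pd.DataFrame:
    """Pivot classified patterns to persons x phenotypes (NaN where absent)."""
    pivot = classified.pivot(index="person_id", columns="phenotype", values="code")
    return pivot.reindex(index=person_ids, columns=phenotypes)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    violations = validate_config(config)
    if violations:
        raise PipelineError("config: " + "; ".join(violations))

    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {"facegrowth": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        _run_stages(config, out, manifest)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> None:
    stages = manifest["stages"]
    table = (lmk.MeasurementTable.from_config(config.measurement_table)
             if config.measurement_table else lmk.MeasurementTable.default())
    phenotype_names = table.names

    # --- stage: generate / ingest -----------------------------------------
    stage = "generate"
    try:
        if config.landmarks_path:
            records = lmk.read_landmarks(config.landmarks_path)
            vectors = [lmk.compute_phenotypes(r, table) for r in records]
            pheno_df = lmk.phenotypes_to_frame(vectors)
            pheno_df["cohort"] = "POP1"
            truth = None
            if config.vcf_path:
                geno, variants, sample_ids = gqc.read_vcf(config.vcf_path)
            else:
                geno = variants = sample_ids = None
        else:
            specs = _make_snp_panel(config)
            n_total = config.n_pop1 + config.n_pop2
            geno, variants = sim.gen_genotypes(
                specs, n_total, sim.component_rng(config.seed, "genotypes"))
            effects = _plant_effects(config, specs, phenotype_names)
            marginals = {p: sim.default_marginals_for(p) for p in phenotype_names}
            codes = sim.gen_pattern_codes(
                geno, variants, phenotype_names, effects, marginals,
                sim.component_rng(config.seed, "pattern_codes"))
            parts, truths, sample_ids = [], [], []
            for label, sl in (("POP1", slice(0, config.n_pop1)),
                              ("POP2", slice(config.n_pop1, n_total))):
                spec = sim.CohortSpec(
                    n_individuals=sl.stop - sl.start,
                    current_age_range=config.current_age_range,
                    photos_per_person_range=config.photos_per_person_range,
                    noise_sd=config.noise_sd, seed=config.seed)
                sub = codes.iloc[sl].reset_index(drop=True)
                part = sim.gen_trajectories(
                    sub, spec, cohort_label=label,
                    rng=sim.component_rng(config.seed, f"trajectories_{label}"))
                part["cohort"] = label
                parts.append(part)
                t = sim.true_patterns_frame(sub, cohort_label=label)
                t["cohort"] = label
                truths.append(t)
                sample_ids += sorted(part["person_id"].unique())
            pheno_df = pd.concat(parts, ignore_index=True)
            truth = pd.concat(truths, ignore_index=True)
            _write(truth, out / "truth_patterns.tsv")
            effects_rows = [(p, s, e) for p, d in effects.items() for s, e in d.items()]
            _write(pd.DataFrame(effects_rows,
                                columns=["phenotype", "snp_id", "effect"]),
                   out / "truth_effects.tsv")
            sim.write_vcf(geno, variants, sample_ids, out / "genotypes.vcf")
        stages[stage] = {"phenotype_records": len(pheno_df),
                         "n_snps": 0 if geno is None else geno.shape[1],
                         "n_samples": 0 if geno is None else geno.shape[0]}
        _write(pheno_df, out / "phenotypes.tsv")
        log.info("stage %s: %s", stage, stages[stage])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # --- stage: measurement QC --------------------------------------------
    stage = "measurement_qc"
    try:
        if config.trim_pct > 0:
            mask = mqc.trim_tails(pheno_df, config.trim_pct, config.trim_pct,
                                  config.trim_method)
            kept = mqc.apply_mask(pheno_df, mask)
        else:
            mask = pheno_df[["person_id", "photo_id", "phenotype"]].assign(
                reason=mqc.KEPT, kept=True)
            kept = pheno_df
        _write(mask, out / "qc_mask.tsv")
        _write(kept, out / "phenotypes_qc.tsv")
        stages[stage] = {"records_in": len(pheno_df), "records_kept": len(kept),
                         "records_flagged": int((~mask["kept"]).sum())}
        log.info("stage %s: %s", stage, stages[stage])
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # --- stage: classify ---------------------------------------------------
    stage = "classify"
    try:
        classified_parts, unc_parts = [], []
        for label, grp in kept.groupby("cohort"):
            # QC may have trimmed a (person, phenotype) current record;
            # those series surface as unclassifiable, not as errors
            trajs, unc = traj.build_trajectories(grp, min_obs=config.min_obs,
                                                 require_current=False)
            cls = traj.classify_cohort(trajs, eps_rel=config.eps_rel,
                                       degree=config.fit_degree)
            cls["cohort"] = label
            unc["cohort"] = label
            classified_parts.append(cls)
            unc_parts.append(unc)
        classified = pd.concat(classified_parts, ignore_index=True)
        unclassifiable = pd.concat(unc_parts, ignore_index=True)
        _write(classified, out / "patterns.tsv")
        _write(unclassifiable, out / "unclassifiable.tsv")
        tables = {}
        for label, grp in classified.groupby("cohort"):
            tables[label] = traj.pattern_table(grp, phenotypes=phenotype_names)
            _write(tables[label], out / f"pattern_table_{label}.tsv")
        stages[stage] = {"classified": len(classified),
                         "unclassifiable": len(unclassifiable)}
        log.info("stage %s: %s", stage, stages[stage])
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # --- stage: genotype QC ------------------------------------------------
    if geno is not None:
        stage = "genotype_qc"
        try:
            stats = [gqc.variant_stats(geno[:, j], variants["snp_id"].iloc[j])
                     for j in range(geno.shape[1])]
            retained, excl = gqc.filter_variants(
                stats, config.call_rate_min, config.maf_min, config.hwe_p_min)
            _write(gqc.stats_frame(stats), out / "variant_stats.tsv")
            _write(excl, out / "variant_exclusions.tsv")
            keep_idx = [j for j, s in enumerate(stats) if s.passed]
            geno_kept = geno[:, keep_idx]
            var_kept = variants.iloc[keep_idx].reset_index(drop=True)
            stages[stage] = {"snps_in": geno.shape[1], "snps_retained": len(retained)}
            log.info("stage %s: %s", stage, stages[stage])
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

        # --- stage: association -------------------------------------------
        stage = "association"
        try:
            codes_mat = _codes_matrix(classified, sample_ids, phenotype_names)
            cohort_of = classified.drop_duplicates("person_id").set_index(
                "person_id")["cohort"]
            is_pop1 = np.array(
                [cohort_of.get(s, "POP1") == "POP1" for s in sample_ids])
            runs = {"combined": np.ones(len(sample_ids), bool),
                    "POP1": is_pop1, "POP2": ~is_pop1}
            results = {}
            for name, sel in runs.items():
                res = assoc.run_association(
                    codes_mat[sel], geno_kept[sel], var_kept,
                    m_tests=config.m_tests,
                    significant_p=config.significant_p,
                    suggestive_p=config.suggestive_p)
                results[name] = res
                _write(res, out / f"assoc_{name}.tsv")
            loci = assoc.cluster_loci(results["combined"], config.cluster_window)
            _write(loci, out / "loci.tsv")
            replicated = assoc.replication_select(
                results["combined"], results["POP1"], results["POP2"],
                combined_p_max=config.suggestive_p,
                pop_p_max=config.replication_pop_p)
            _write(replicated, out / "replication_snps.tsv")
            if config.make_plots:
                assoc.plot_manhattan(results["combined"], out / "manhattan.png")
                assoc.plot_qq(results["combined"], out / "qq.png")
            stages[stage] = {
                "tests": len(results["combined"]),
                "tiered": int(results["combined"]["tier"].isin(
                    ["significant", "suggestive"]).sum()),
                "replicated": int(replicated["selected"].sum()),
            }
            log.info("stage %s: %s", stage, stages[stage])
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # --- stage: cohort replication ----------------------------------------
    if not config.landmarks_path:
        stage = "cohort_replication"
        try:
            report = repl.modal_concordance(tables["POP1"], tables["POP2"])
            _write(report.per_phenotype, out / "concordance.tsv")
            (out / "concordance.txt").write_text(report.summary() + "\n")
            stages[stage] = {"n_agree": report.n_agree,
                             "n_phenotypes": report.n_phenotypes,
                             "fraction_agree": report.fraction_agree}
            log.info("stage %s: %s", stage, stages[stage])
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc


def setup_logging(verbose: bool = False, log_file: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)
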