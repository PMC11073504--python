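"""End-to-end orchestration: simulate/load -> concordance -> enrichment ->
task statistics -> growth associations, from one declarative config.

Every stage writes its tables under the output directory and appends itself
to ``MANIFEST.txt`` once complete, so a failed run preserves the partial
outputs of the stages that finished.  A JSON report collects the test
summaries, the configuration, seeds and library versions for provenance.
Identical configs produce byte-identical outputs: every source of randomness
derives from the master seed through fixed offsets.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import association, concordance, enrichment, taskstats
from .cohort import CohortParams, SyntheticTruth, generate_cohort
from .errors import ParameterError
from .io import (
    AbundanceMatrix,
    GeneSetCollection,
    GrowthTable,
    dump_json,
    read_abundance,
    read_gmt,
    read_growth,
    write_abundance,
    write_gmt,
    write_growth,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"
STAGES = ("simulate", "concordance", "enrich", "taskstats", "associate")


@dataclass
class InputPaths:
    mrna: str
    protein: str
    gmt: str
    growth: str


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Exactly one of ``simulate`` (cohort parameters) or ``inputs`` (paths to
    existing TSV/GMT files) must be present.
    """

    outdir: str = "results/pipeline"
    seed: int = 7
    simulate: Optional[CohortParams] = None
    inputs: Optional[InputPaths] = None
    method: str = "pearson"
    log_transform: bool = True
    n_perm: int = 1000
    n_boot: int = 10_000
    exponent: float = 1.0
    min_set_size: int = 5
    sign_convention: str = "mrna_minus_protein"
    fdr_threshold: float = 0.2
    random_set_size: int = 500
    bootstrap_sample_size: Optional[int] = None
    plots: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ParameterError("config must contain exactly one of 'simulate' or 'inputs'")
        if self.sign_convention not in taskstats.SIGN_CONVENTIONS:
            raise ParameterError(f"sign_convention must be one of {taskstats.SIGN_CONVENTIONS}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        inputs = raw.pop("inputs", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        cfg_seed = int(raw.get("seed", 7))
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", cfg_seed)
            if "hallmark_sizes" in sim and sim["hallmark_sizes"] is not None:
                sim["hallmark_sizes"] = list(sim["hallmark_sizes"])
            sim = CohortParams(**sim)
        if inputs is not None:
            inputs = InputPaths(**inputs)
        return cls(simulate=sim, inputs=inputs, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            d["simulate"]["hallmark_sizes"] = (
                list(self.simulate.hallmark_sizes)
                if self.simulate.hallmark_sizes is not None
                else None
            )
            d["simulate"]["gene_noise_sd_range"] = list(self.simulate.gene_noise_sd_range)
        return d


def default_config(outdir: str = "results/pipeline", seed: int = 7) -> PipelineConfig:
    """The default synthetic-cohort configuration."""
    return PipelineConfig(outdir=outdir, seed=seed, simulate=CohortParams(seed=seed))


def _derive_seed(seed: int, offset: int) -> int:
    return int(np.random.SeedSequence([int(seed), offset]).generate_state(1)[0] % (2**31))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        mrna, protein, sets, growth, truth = generate_cohort(config.simulate)
        write_abundance(mrna, outdir / "mrna.tsv")
        write_abundance(protein, outdir / "protein.tsv")
        write_gmt(sets, outdir / "hallmarks.gmt")
        write_growth(growth, outdir / "growth.tsv")
        truth.to_json(outdir / "truth.json")
    else:
        paths = config.inputs
        for p in (paths.mrna, paths.protein, paths.gmt, paths.growth):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        mrna = read_abundance(paths.mrna, "mrna")
        protein = read_abundance(paths.protein, "protein")
        sets = read_gmt(paths.gmt)
        growth = read_growth(paths.growth)
        truth = None
    return mrna, protein, sets, growth, truth


def stage_concordance(
    config: PipelineConfig,
    outdir: Path,
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    sets: GeneSetCollection,
) -> Dict:
    summaries: Dict = {}
    for method in ("pearson", "spearman"):
        corr = concordance.cross_correlation(
            mrna, protein, method=method, log_transform=config.log_transform
        )
        corr.values.to_csv(
            outdir / f"correlation_{method}.tsv", sep="\t",
            index_label="mrna_cell", float_format=FLOAT_FORMAT,
        )
        welch, ks = concordance.same_vs_other(corr)
        summaries[method] = {
            "mean_same_cell": float(np.nanmean(corr.same_cell())),
            "mean_other_cell": float(np.nanmean(corr.other_cell())),
            "welch_t": welch.to_dict(),
            "ks": ks.to_dict(),
        }

    shared = [g for g in mrna.gene_ids if g in set(protein.gene_ids)]
    n_random = min(config.random_set_size, len(shared))
    if n_random < config.random_set_size:
        logger.warning(
            "random set size %d clipped to shared universe size %d",
            config.random_set_size, n_random,
        )
    random_members = concordance.sample_random_set(
        shared, n_random, _derive_seed(config.seed, 71)
    )
    with_random = GeneSetCollection(
        universe=list(sets.universe),
        sets={**sets.sets, "random_set": random_members},
    )
    setwise = concordance.setwise_correlation(
        mrna, protein, with_random, method=config.method, log_transform=config.log_transform
    )
    _write(setwise, outdir / "setwise_correlations.tsv")
    rand = setwise[setwise["set_name"] == "random_set"].set_index("cell_id")["r"]
    hall = setwise[setwise["set_name"] != "random_set"]
    per_set, anova = concordance.hallmark_vs_random(hall, rand)
    summaries["hallmark_vs_random"] = {
        "wilcoxon": {name: t.to_dict() for name, t in per_set.items()},
        "anova": anova.to_dict(),
        "median_hallmark_r": float(np.nanmedian(hall["r"])),
        "median_random_r": float(np.nanmedian(rand)),
    }
    return summaries


def stage_enrich(
    config: PipelineConfig,
    outdir: Path,
    mrna: AbundanceMatrix,
    protein: AbundanceMatrix,
    sets: GeneSetCollection,
) -> pd.DataFrame:
    frames = []
    for matrix, offset in ((mrna, 301), (protein, 302)):
        frames.append(
            enrichment.enrich_matrix(
                matrix, sets,
                n_perm=config.n_perm,
                seed=_derive_seed(config.seed, offset),
                exponent=config.exponent,
                min_size=config.min_set_size,
            )
        )
    records = pd.concat(frames, ignore_index=True)
    _write(records, outdir / "enrichment_records.tsv")
    return records


def stage_taskstats(
    config: PipelineConfig, outdir: Path, records: pd.DataFrame
) -> tuple:
    rec_m = records[records["modality"] == "mrna"]
    rec_p = records[records["modality"] == "protein"]
    stats_table = taskstats.compute_task_stats(rec_m, rec_p, config.sign_convention)
    _write(stats_table.delta, outdir / "delta.tsv")
    _write(stats_table.range, outdir / "range.tsv")
    tests = taskstats.bootstrap_all_sets(
        rec_m, rec_p,
        n_boot=config.n_boot,
        sample_size=config.bootstrap_sample_size,
        seed=_derive_seed(config.seed, 401),
        sign_convention=config.sign_convention,
    )
    _write(taskstats.difference_tests_to_frame(tests), outdir / "bootstrap_tests.tsv")
    return stats_table, tests


def stage_associate(
    config: PipelineConfig,
    outdir: Path,
    stats_table: taskstats.TaskStatTable,
    growth: GrowthTable,
) -> Dict:
    records = association.division_associations(
        stats_table.delta, stats_table.range, growth
    ) + association.inhibition_associations(stats_table.delta, stats_table.range, growth)
    _write(association.records_to_frame(records), outdir / "associations.tsv")

    effects: List = []
    try:
        effects.append(association.fixed_effect_model(stats_table.delta, growth))
    except Exception as exc:  # noqa: BLE001 - recorded, not fatal
        logger.warning("fixed-effect model failed: %s", exc)
    effects.extend(association.per_hallmark_effects(stats_table.delta, growth))
    _write(association.effects_to_frame(effects), outdir / "effects.tsv")

    rng_m = stats_table.range.loc[stats_table.range["modality"] == "mrna", "range"]
    rng_p = stats_table.range.loc[stats_table.range["modality"] == "protein", "range"]
    summaries: Dict = {}
    if len(rng_m) >= 2 and len(rng_p) >= 2:
        summaries["range_ecdf_protein_vs_mrna"] = association.ecdf_compare(
            rng_p, rng_m, alternative="two_sided"
        ).to_dict()
    summaries["fixed_effect"] = (
        dataclasses.asdict(effects[0]) if effects and effects[0].model == "pooled_fixed_effect"
        else None
    )
    summaries["associations"] = association.records_to_frame(records).to_dict("records")
    if config.plots:
        association.plot_delta_division(stats_table.delta, growth, outdir / "delta_division.png")
    return summaries


# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run all stages; returns the report dict (also written as report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "MANIFEST.txt"
    manifest.write_text("")
    completed: List[str] = []

    def done(stage: str) -> None:
        completed.append(stage)
        manifest.write_text("\n".join(completed) + "\n")

    report: Dict = {
        "config": config.to_dict(),
        "versions": _versions(),
        "stages": {},
    }
    try:
        mrna, protein, sets, growth, truth = stage_simulate(config, outdir)
        done("simulate")
        report["stages"]["concordance"] = stage_concordance(config, outdir, mrna, protein, sets)
        done("concordance")
        records = stage_enrich(config, outdir, mrna, protein, sets)
        n_sig = int(
            (records.loc[~records["flagged"].astype(bool), "fdr_q"] < config.fdr_threshold).sum()
        )
        report["stages"]["enrich"] = {
            "n_records": int(len(records)),
            "n_significant": n_sig,
            "fdr_threshold": config.fdr_threshold,
        }
        done("enrich")
        stats_table, tests = stage_taskstats(config, outdir, records)
        report["stages"]["taskstats"] = {
            "sign_convention": config.sign_convention,
            "difference_tests": taskstats.difference_tests_to_frame(tests).to_dict("records"),
        }
        done("taskstats")
        report["stages"]["associate"] = stage_associate(config, outdir, stats_table, growth)
        done("associate")
    except Exception:
        logger.error("pipeline failed after stages: %s", completed)
        raise
    finally:
        dump_json(report, outdir / "report.json")
    return report


def _versions() -> Dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "hallmarktasks": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
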