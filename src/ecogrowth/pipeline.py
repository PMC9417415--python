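"""End-to-end orchestration: synthesize -> extract -> embed -> predict ->
sensitivity -> simulate -> report.

Stages communicate exclusively through declared file artifacts in the run
directory, so any stage can be re-run or disabled independently; a JSON
manifest records seeds, package versions and artifact hashes, and
re-running a manifest reproduces all deterministic outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import aa_usage, growth, medium_space, ml, sensitivity, simulate, synthetic

STAGE_ORDER = ("synth", "extract", "embed", "ml", "sensitivity", "simulate", "aa")

#: File artifacts each stage needs, mapped to the stage that produces them.
_REQUIRES = {
    "extract": {"curves.csv": "synth"},
    "embed": {"design.csv": "synth", "parameters.csv": "extract"},
    "ml": {"design.csv": "synth", "parameters.csv": "extract"},
    "sensitivity": {"design.csv": "synth", "parameters.csv": "extract"},
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run; safe small-scale defaults."""

    outdir: str = "ecogrowth_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGE_ORDER[:-1]))
    # synth
    n_components: int = 8
    levels_per_gradient: int = 6
    n_backgrounds: int = 3
    noise_sd: float = 0.001
    n_replicates: int = 4
    # extract
    cv_threshold: float = growth.DEFAULT_CV_THRESHOLD
    # embed
    k_clusters: int = 4
    # ml
    parameter: str = "rate"
    model: str = "gbdt"
    n_estimators: int = 100
    ml_grid: dict | None = field(
        default_factory=lambda: {"learning_rate": [0.05, 0.1, 0.2],
                                 "max_depth": [2, 3]})
    kde_bandwidth: float = 0.3
    # simulate
    n_sims: int = 1000
    n_sims_correlated: int = 10_000
    c_tau_r: float = 0.74
    c_tau_k: float = 0.58
    c_r_k: float = 0.17
    # aa (optional external inputs)
    genbank_path: str | None = None
    expression_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _need(outdir: Path, stage: str) -> dict[str, Path]:
    paths = {}
    for fname, producer in _REQUIRES.get(stage, {}).items():
        p = outdir / fname
        if not p.exists():
            raise PipelineError(
                f"stage {stage!r} needs {fname!r}; enable stage {producer!r} "
                "or place the file in the run directory")
        paths[fname] = p
    return paths


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_synth(cfg: PipelineConfig, outdir: Path) -> list[str]:
    design = synthetic.generate_design(
        n_components=cfg.n_components, levels_per_gradient=cfg.levels_per_gradient,
        n_backgrounds=cfg.n_backgrounds, seed=cfg.seed)
    determinants = {
        "tau": design.component_names[0],
        "rate": design.component_names[min(1, cfg.n_components - 1)],
        "capacity": design.component_names[min(2, cfg.n_components - 1)],
    }
    model = synthetic.ResponseModel(determinant_map=determinants,
                                    noise_sd=cfg.noise_sd)
    truth = synthetic.ground_truth_parameters(design, model)
    curves = synthetic.simulate_curves(truth, noise_sd=cfg.noise_sd,
                                       n_replicates=cfg.n_replicates,
                                       seed=cfg.seed)
    synthetic.write_design_csv(design, outdir / "design.csv")
    truth.to_csv(outdir / "ground_truth.csv")
    growth.write_curves_long(curves, outdir / "curves.csv")
    (outdir / "determinants.json").write_text(json.dumps(determinants, indent=1))
    return ["design.csv", "ground_truth.csv", "curves.csv", "determinants.json"]


def stage_extract(cfg: PipelineConfig, outdir: Path) -> list[str]:
    paths = _need(outdir, "extract")
    curves = growth.read_curves_long(paths["curves.csv"])
    table = growth.parameters_table(curves, cv_threshold=cfg.cv_threshold)
    table.to_csv(outdir / "parameters.csv")
    return ["parameters.csv"]


def stage_embed(cfg: PipelineConfig, outdir: Path) -> list[str]:
    paths = _need(outdir, "embed")
    design = synthetic.read_design_csv(paths["design.csv"])
    params = pd.read_csv(paths["parameters.csv"], index_col="combination_id")
    matrix = medium_space.normalize_concentrations(design)
    scores = medium_space.pca_scores(matrix)
    medium_space.kmeans_clusters(scores, k=cfg.k_clusters, seed=cfg.seed)
    out = scores.scores.copy()
    out["cluster"] = scores.labels
    out.to_csv(outdir / "scores.csv")
    medium_space.correlate_with_parameters(scores, params).to_csv(
        outdir / "correlations.csv", index=False)
    return ["scores.csv", "correlations.csv"]


def stage_ml(cfg: PipelineConfig, outdir: Path) -> list[str]:
    paths = _need(outdir, "ml")
    design = synthetic.read_design_csv(paths["design.csv"])
    params = pd.read_csv(paths["parameters.csv"], index_col="combination_id")
    features = ml.build_features(design, params, cfg.parameter)
    evaluation = ml.nested_cv_evaluate(features, model=cfg.model, grid=cfg.ml_grid,
                                       seed=cfg.seed, n_estimators=cfg.n_estimators)
    evaluation.fold_metrics.to_csv(outdir / "evaluation.csv")
    profile = ml.gbdt_importance(features, grid=cfg.ml_grid, seed=cfg.seed,
                                 n_estimators=cfg.n_estimators)
    profile.mean.rename("importance").to_csv(outdir / "importance.csv")
    split = ml.split_bimodal(features.y, bw=cfg.kde_bandwidth)
    split_payload = {"parameter": cfg.parameter, "separable": split.separable,
                     "threshold": split.threshold,
                     "n_low": None if split.low_ids is None else len(split.low_ids),
                     "n_high": None if split.high_ids is None else len(split.high_ids)}
    (outdir / "split.json").write_text(json.dumps(split_payload, indent=1))
    return ["evaluation.csv", "importance.csv", "split.json"]


def stage_sensitivity(cfg: PipelineConfig, outdir: Path) -> list[str]:
    paths = _need(outdir, "sensitivity")
    design = synthetic.read_design_csv(paths["design.csv"])
    params = pd.read_csv(paths["parameters.csv"], index_col="combination_id")
    table = sensitivity.component_sensitivity_table(design, params)
    table.to_csv(outdir / "sensitivity.csv")
    sensitivity.power_law_summary(table).to_csv(outdir / "power_law.csv")
    return ["sensitivity.csv", "power_law.csv"]


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[str]:
    sim_cfg = simulate.SimulationConfig(
        n_sims=cfg.n_sims, n_sims_correlated=cfg.n_sims_correlated,
        c_tau_r=cfg.c_tau_r, c_tau_k=cfg.c_tau_k, c_r_k=cfg.c_r_k, seed=cfg.seed)
    curves = [simulate.survival_probability(s, sim_cfg)
              for s in ("single", "triple_independent")]
    pd.concat(curves, ignore_index=True).to_csv(outdir / "survival.csv", index=False)
    comparison = simulate.compare_final_sizes(sim_cfg)
    pd.DataFrame(comparison.sizes).to_csv(outdir / "final_sizes.csv", index=False)
    summary = {"u_statistic": comparison.u_statistic,
               "p_value": comparison.p_value,
               "median_difference": comparison.median_difference}
    (outdir / "simulation_summary.json").write_text(json.dumps(summary, indent=1))
    return ["survival.csv", "final_sizes.csv", "simulation_summary.json"]


def stage_aa(cfg: PipelineConfig, outdir: Path) -> list[str]:
    if cfg.genbank_path is None:
        raise PipelineError("stage 'aa' needs genbank_path in the config")
    counts = aa_usage.count_amino_acids(cfg.genbank_path)
    expression = (aa_usage.read_expression_tsv(cfg.expression_path)
                  if cfg.expression_path else None)
    profile = aa_usage.relative_abundance(counts, expression)
    out = profile.fractions.rename("fraction").to_frame()
    out.index.name = "amino_acid"
    out.to_csv(outdir / "aa_profile.csv")
    (outdir / "bcaa_enrichment.json").write_text(
        json.dumps(aa_usage.bcaa_enrichment(profile), indent=1))
    return ["aa_profile.csv", "bcaa_enrichment.json"]


_STAGE_FUNCS = {
    "synth": stage_synth, "extract": stage_extract, "embed": stage_embed,
    "ml": stage_ml, "sensitivity": stage_sensitivity,
    "simulate": stage_simulate, "aa": stage_aa,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and write a manifest.

    The manifest records the package version, the seed, per-stage wall
    times and the SHA-256 hash of every artifact, and is returned as well
    as written to ``manifest.json`` in the run directory.
    """
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config": {k: v for k, v in vars(config).items()},
                "stages": {}}
    log_path = outdir / "run_log.jsonl"
    with log_path.open("w") as log:
        for stage in STAGE_ORDER:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            artifacts = _STAGE_FUNCS[stage](config, outdir)
            elapsed = time.perf_counter() - t0
            hashes = {a: _sha256(outdir / a) for a in artifacts}
            manifest["stages"][stage] = {"artifacts": hashes,
                                         "seconds": round(elapsed, 3)}
            log.write(json.dumps({"stage": stage, "seconds": round(elapsed, 3),
                                  "artifacts": artifacts}) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
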