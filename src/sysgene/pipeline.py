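"""Config-driven end-to-end orchestration.

A run directory accumulates stage outputs under fixed names, so any stage
can be re-run from its upstream files:

    simulate -> genotypes.tsv, loci.tsv, quality.tsv, phenotype.tsv,
                items.tsv, truth.json
    qc       -> genotypes_qc.tsv, loci_qc.tsv, qc_report.json,
                coded_design.tsv
    screen   -> screen.tsv, screen.json
    fit      -> models.json, coefficients.tsv, comparisons.tsv
    permute  -> permutation.json
    report   -> descriptives.tsv, correlations.tsv, permutation_plot.png

``manifest.json`` records the resolved configuration, seed and package
version for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as sio
from .measures import ScaleData, correlation_table, cronbach_alpha, descriptives
from .permutation import MODELS, SCOPES, run_null_pipeline
from .qc import code_loci, run_qc
from .regression import (
    add_environment,
    build_model1,
    build_model2,
    compare_models,
    comparison_table,
    fit_subsystems,
)
from .screen import screen_panel, screen_table
from .simulate import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # simulation (used unless external inputs are supplied)
    n_subjects: int = 480
    genotypes: str = ""  # external genotype TSV (optional)
    loci: str = ""  # external locus TSV
    phenotype: str = ""  # external phenotype/environment TSV
    # thresholds
    max_missing: float = 0.10
    min_quality: float = 0.25
    min_group: int = 10
    ld_r2: float = 0.8
    alpha_screen: float = 0.05
    alpha_enter: float = 0.05
    with_env: bool = True
    B: int = 1000

    def __post_init__(self) -> None:
        checks = [
            0 < self.max_missing < 1,
            0 <= self.min_quality <= 1,
            self.min_group >= 1,
            0 < self.ld_r2 <= 1,
            0 < self.alpha_screen < 1,
            0 < self.alpha_enter < 1,
            self.B >= 1,
        ]
        if not all(checks):
            raise ValueError("threshold out of valid range in RunConfig")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def write_manifest(config: RunConfig, stage: str) -> None:
    out = _outdir(config)
    path = out / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": []}
    blob = json.dumps(config.to_dict(), sort_keys=True)
    manifest.update(
        {
            "config": config.to_dict(),
            "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": config.seed,
            "version": __version__,
        }
    )
    if stage not in manifest["stages"]:
        manifest["stages"].append(stage)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig) -> Path:
    out = _outdir(config)
    bundle = simulate_cohort(CohortConfig(n_subjects=config.n_subjects), seed=config.seed)
    sio.write_genotypes_tsv(
        bundle.genotypes, out / "genotypes.tsv", out / "loci.tsv", out / "quality.tsv"
    )
    sio.write_phenotype_tsv(bundle.phenotype, bundle.environment, out / "phenotype.tsv")
    if bundle.items is not None:
        sio.write_items_tsv(bundle.items, out / "items.tsv")
    sio.write_json(
        {
            "intercept": bundle.truth.intercept,
            "additive_effects": bundle.truth.additive_effects,
            "interaction_effects": {f"{a}|{b}": v for (a, b), v in bundle.truth.interaction_effects.items()},
            "environment_effects": bundle.truth.environment_effects,
            "noise_sd": bundle.truth.noise_sd,
        },
        out / "truth.json",
    )
    write_manifest(config, "simulate")
    return out


def _load_inputs(config: RunConfig, qc_stage: bool) -> tuple:
    out = _outdir(config)
    if qc_stage:
        g = sio.read_genotypes_tsv(
            config.genotypes or out / "genotypes.tsv",
            config.loci or out / "loci.tsv",
            out / "quality.tsv",
        )
    else:
        g = sio.read_genotypes_tsv(out / "genotypes_qc.tsv", out / "loci_qc.tsv")
    pheno, env = sio.read_phenotype_tsv(config.phenotype or out / "phenotype.tsv")
    return g, pheno, env


def stage_qc(config: RunConfig) -> Path:
    out = _outdir(config)
    g, _, _ = _load_inputs(config, qc_stage=True)
    g_qc, report = run_qc(
        g,
        max_missing=config.max_missing,
        min_quality=config.min_quality,
        min_group=config.min_group,
        ld_r2=config.ld_r2,
    )
    sio.write_genotypes_tsv(g_qc, out / "genotypes_qc.tsv", out / "loci_qc.tsv")
    sio.write_qc_report(report, out / "qc_report.json")
    sio.write_coded_design(code_loci(g_qc), out / "coded_design.tsv")
    write_manifest(config, "qc")
    return out


def stage_screen(config: RunConfig) -> Path:
    out = _outdir(config)
    g, pheno, _ = _load_inputs(config, qc_stage=False)
    pheno = pheno.reindex(g.subjects)
    results = screen_panel(g, pheno, alpha_screen=config.alpha_screen)
    screen_table(results).to_csv(out / "screen.tsv", sep="\t", index=False)
    sio.write_json(
        {"selected": [r.locus for r in results if r.selected], "alpha": config.alpha_screen},
        out / "screen.json",
    )
    write_manifest(config, "screen")
    return out


def stage_fit(config: RunConfig) -> Path:
    out = _outdir(config)
    g, pheno, env = _load_inputs(config, qc_stage=False)
    pheno = pheno.reindex(g.subjects)
    env = env.reindex(g.subjects)
    selected = json.loads((out / "screen.json").read_text())["selected"]
    if not selected:
        raise ValueError("no loci passed screening; nothing to fit")
    design = code_loci(g)
    m1 = build_model1(design, selected, pheno)
    m2 = build_model2(design, selected, pheno, alpha_enter=config.alpha_enter, model1=m1)
    subs = fit_subsystems(design, selected, pheno, alpha_enter=config.alpha_enter)
    models = {
        "model1": m1.to_dict(),
        "model2": m2.to_dict(),
        "subsystems": {k: v.to_dict() for k, v in subs.items()},
    }
    comp_rows = [("model1", m1, None), ("model2", m2, compare_models(m1, m2))]
    if config.with_env:
        env_m1, comp1 = add_environment(pheno, m1, env, alpha_enter=config.alpha_enter)
        env_m2, comp2 = add_environment(pheno, m2, env, alpha_enter=config.alpha_enter)
        models["model1_env"] = env_m1.to_dict()
        models["model2_env"] = env_m2.to_dict()
        comp_rows += [("model1+env", env_m1, comp1), ("model2+env", env_m2, comp2)]
    sio.write_json(models, out / "models.json")
    coef = pd.concat(
        {
            "model1": m1.coefficient_table(),
            "model2": m2.coefficient_table(),
        },
        names=["model", "regressor"],
    )
    coef.to_csv(out / "coefficients.tsv", sep="\t")
    comparison_table(comp_rows).to_csv(out / "comparisons.tsv", sep="\t", index=False)
    write_manifest(config, "fit")
    return out


def stage_permute(config: RunConfig) -> Path:
    out = _outdir(config)
    g, pheno, _ = _load_inputs(config, qc_stage=False)
    pheno = pheno.reindex(g.subjects)
    result = run_null_pipeline(
        g,
        pheno,
        B=config.B,
        seed=config.seed,
        alpha_screen=config.alpha_screen,
        alpha_enter=config.alpha_enter,
    )
    sio.write_json(result.to_dict(), out / "permutation.json")
    write_manifest(config, "permute")
    return out


def stage_report(config: RunConfig) -> Path:
    out = _outdir(config)
    _, pheno, env = _load_inputs(config, qc_stage=False)
    variables = {"hsp_total": pheno, **{c: env[c] for c in env.columns}}
    desc = descriptives(variables)
    items_path = out / "items.tsv"
    if items_path.exists():
        items = sio.read_items_tsv(items_path)
        desc.loc[desc["variable"] == "hsp_total", "cronbach_alpha"] = cronbach_alpha(
            ScaleData(items=items, scale_name="hsp")
        )
    desc.to_csv(out / "descriptives.tsv", sep="\t", index=False)
    correlation_table(variables).to_csv(out / "correlations.tsv", sep="\t", index=False)
    perm_path = out / "permutation.json"
    if perm_path.exists():
        plot_null_distributions(json.loads(perm_path.read_text()), out / "permutation_plot.png")
    write_manifest(config, "report")
    return out


def plot_null_distributions(perm: dict, path) -> None:
    """Histogram of null R² with the observed value marked, per model/scope."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(MODELS), len(SCOPES), figsize=(3 * len(SCOPES), 5), squeeze=False)
    for i, model in enumerate(MODELS):
        for j, scope in enumerate(SCOPES):
            ax = axes[i][j]
            nulls = perm["null_R2"][model][scope]
            ax.hist(nulls, bins=30, color="0.7")
            ax.axvline(perm["observed"][model][scope]["R2"], color="k")
            ax.set_title(f"{model} / {scope}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "screen": stage_screen,
    "fit": stage_fit,
    "permute": stage_permute,
    "report": stage_report,
}


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order; returns the run directory."""
    if config.genotypes and not Path(config.genotypes).exists():
        raise FileNotFoundError(config.genotypes)
    out = _outdir(config)
    order = ["simulate", "qc", "screen", "fit", "permute", "report"]
    if config.genotypes:
        order = order[1:]
    for name in order:
        logger.info("stage %s", name)
        STAGES[name](config)
    return out
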