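"""End-to-end orchestration of the concordance analysis from one config.

A single YAML document describes a run: either a simulation section (the
bundled generator) or paths to an existing beta matrix / sample sheet /
annotation, an ``analysis`` section surfacing every threshold, and the
stages to execute.  Stages run in dependency order; each writes TSV
outputs whose header comments record the config hash and seed, so a rerun
with the same config is byte-identical for deterministic stages.  A stage
failure is recorded in the run manifest and its dependents are skipped,
while independent stages still run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import categories as cat
from . import concordance as conc
from . import enrich as enr
from . import qc
from . import structure as struct
from . import surrogate as surr
from .core import (
    AnalysisConfig,
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    beta_to_m,
    read_beta_matrix,
    write_beta_matrix,
)
from .exceptions import ConfigError, OculoConcordError
from .simulate import SimConfig, SimResult, simulate_dataset, write_fixture_bundle

__all__ = ["PipelineRun", "load_config", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "filter",
    "categories",
    "concordance",
    "surrogate",
    "structure",
    "enrich",
)

# which earlier stages each stage needs to have succeeded
_DEPS = {
    "simulate": (),
    "filter": (),
    "categories": ("filter",),
    "concordance": ("filter",),
    "surrogate": ("filter",),
    "structure": ("filter",),
    "enrich": ("filter", "surrogate", "structure"),
}

_TOP_KEYS = {
    "seed",
    "output_dir",
    "stages",
    "simulate",
    "inputs",
    "analysis",
    "filter",
    "surrogate",
    "structure",
    "enrich",
}


@dataclass
class PipelineRun:
    """Record of one pipeline execution."""

    config: dict
    config_hash: str
    seed: int
    output_dir: Path
    outputs: dict[str, list[str]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    results: dict[str, object] = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "status": self.status,
            "outputs": self.outputs,
            "errors": self.errors,
        }


def load_config(path_or_dict) -> dict:
    """Load and schema-validate a pipeline config (YAML path or dict)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs either a 'simulate' or an 'inputs' section")
    # constructing the validated objects IS the schema check
    _build_analysis_config(cfg)
    if "simulate" in cfg:
        _build_sim_config(cfg)
    return cfg


def _build_analysis_config(cfg: dict) -> AnalysisConfig:
    section = dict(cfg.get("analysis") or {})
    section.setdefault("rng_seed", int(cfg.get("seed", 0)))
    if "variability_quantiles" in section:
        section["variability_quantiles"] = tuple(section["variability_quantiles"])
    try:
        return AnalysisConfig(**section)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid analysis section: {exc}") from exc


def _build_sim_config(cfg: dict) -> SimConfig:
    section = dict(cfg.get("simulate") or {})
    section.setdefault("seed", int(cfg.get("seed", 0)))
    if "tissues" in section:
        section["tissues"] = tuple(section["tissues"])
    if "class_weights" in section:
        section["class_weights"] = tuple(section["class_weights"])
    try:
        return SimConfig(**section)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulate section: {exc}") from exc


def _write_tsv(df: pd.DataFrame, path: Path, tag: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {tag}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA", float_format="%.10g")


def run_pipeline(config, output_dir: str | Path | None = None) -> PipelineRun:
    """Execute the requested stages and write all outputs + a manifest.

    ``config`` is a YAML path or dict (see :func:`load_config`).  Returns
    the :class:`PipelineRun`; in-memory stage results stay available under
    ``run.results`` for programmatic use.
    """
    cfg = load_config(config)
    acfg = _build_analysis_config(cfg)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(output_dir or cfg.get("output_dir", "oculoconcord_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"oculoconcord config_hash={acfg.config_hash()} seed={seed}"
    requested = cfg.get("stages", "all")
    stages = list(STAGES) if requested in ("all", None) else list(requested)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    if "inputs" in cfg and "simulate" not in cfg:
        stages = [s for s in stages if s != "simulate"]

    run = PipelineRun(
        config=cfg, config_hash=acfg.config_hash(), seed=seed, output_dir=out_dir
    )
    state: dict[str, object] = {"acfg": acfg}

    for stage in STAGES:
        if stage not in stages:
            run.status[stage] = "not_requested"
            continue
        if any(run.status.get(d) in ("failed", "skipped") for d in _DEPS[stage]):
            run.status[stage] = "skipped"
            continue
        try:
            _run_stage(stage, cfg, acfg, state, run, out_dir, tag)
            run.status[stage] = "ok"
        except OculoConcordError as exc:
            logger.error("stage %s failed: %s", stage, exc)
            run.status[stage] = "failed"
            run.errors[stage] = f"{type(exc).__name__}: {exc}"
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(run.manifest(), fh, indent=2)
    return run


def _load_inputs(cfg: dict) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation, pd.DataFrame | None]:
    paths = cfg["inputs"]
    beta = read_beta_matrix(paths["beta"])
    sheet = SampleSheet.read_csv(paths["samples"])
    ann = ProbeAnnotation.read_tsv(paths["annotation"])
    detp = None
    if paths.get("detection_p"):
        detp = pd.read_csv(paths["detection_p"], sep="\t", index_col=0, comment="#")
    return beta, sheet, ann, detp


def _run_stage(stage, cfg, acfg, state, run, out_dir, tag) -> None:
    outputs: list[str] = []

    def save(df, name, index=True):
        path = out_dir / name
        _write_tsv(df, path, tag, index)
        outputs.append(str(path))

    if stage == "simulate":
        sim = simulate_dataset(_build_sim_config(cfg))
        bundle = out_dir / "simulated"
        write_fixture_bundle(sim, bundle)
        outputs.append(str(bundle))
        state["sim"] = sim
        state["raw"] = (sim.beta, sim.sheet, sim.annotation, sim.detection_p)
        run.results["simulate"] = sim

    elif stage == "filter":
        if "raw" not in state:
            state["raw"] = _load_inputs(cfg)
        beta, sheet, ann, detp = state["raw"]
        retain_sex = bool((cfg.get("filter") or {}).get("retain_sex", True))
        filtered, report = qc.filter_probes(beta, ann, detp, acfg, retain_sex)
        state["beta"] = filtered
        state["sheet"] = sheet
        state["ann"] = ann
        write_beta_matrix(filtered, out_dir / "beta_filtered.tsv", tag)
        outputs.append(str(out_dir / "beta_filtered.tsv"))
        save(qc.summarize_filtering(report), "filter_summary.tsv", index=False)
        run.results["filter"] = report

    elif stage == "categories":
        beta, sheet = state["beta"], state["sheet"]
        means = cat.tissue_mean_beta(beta, sheet)
        classes = cat.categorize_probes(means, acfg)
        save(means, "tissue_mean_beta.tsv")
        save(classes, "tissue_classes.tsv")
        overlaps = pd.concat(
            [cat.overlap_counts_frame(classes, c) for c in cat.CLASSES],
            ignore_index=True,
        )
        save(overlaps, "class_overlap_counts.tsv", index=False)
        joints = []
        eye_tissues = [t for t in sheet.tissues if t != "blood"]
        for t in eye_tissues:
            j = cat.joint_blood_eye_classes(classes, t, state["ann"])
            j.insert(0, "eye_tissue", t)
            joints.append(j)
        if joints:
            save(pd.concat(joints, ignore_index=True), "joint_blood_eye_classes.tsv", index=False)
        run.results["categories"] = {"means": means, "classes": classes, "overlaps": overlaps}

    elif stage == "concordance":
        beta, sheet = state["beta"], state["sheet"]
        scm = conc.sample_pairwise_spearman(beta)
        summary = conc.tissue_pair_summary(scm, sheet)
        newick = conc.hierarchical_cluster(scm)
        save(scm, "sample_correlations.tsv")
        save(summary, "tissue_pair_summary.tsv", index=False)
        nwk_path = out_dir / "sample_dendrogram.nwk"
        nwk_path.write_text(newick + "\n")
        outputs.append(str(nwk_path))
        run.results["concordance"] = {"scm": scm, "summary": summary, "newick": newick}

    elif stage == "surrogate":
        beta, sheet = state["beta"], state["sheet"]
        section = cfg.get("surrogate") or {}
        eye_tissues = section.get(
            "eye_tissues", [t for t in sheet.tissues if t != "blood"]
        )
        exact_p = bool(section.get("exact_p", False))
        variable = surr.blood_variable_probes(beta, sheet, acfg)
        save(variable.table, "blood_variable_probes.tsv")
        per_tissue = {}
        null_stats = []
        for t in eye_tissues:
            res = surr.matched_probe_correlation(beta, sheet, variable, t, acfg, exact_p)
            per_tissue[t] = res
            save(res, f"matched_correlation_{t}.tsv")
            null = surr.permutation_null(beta, sheet, variable, t, acfg)
            u, z, p = surr.compare_to_null(res, null)
            null_stats.append(
                {
                    "tissue": t,
                    "n_matched": int(res["rho"].notna().sum()),
                    "n_null": int(null.values.size),
                    "null_mean": float(null.values.mean()) if null.values.size else float("nan"),
                    "U": u,
                    "z": z,
                    "p_value": p,
                }
            )
        save(pd.DataFrame(null_stats), "null_comparison.tsv", index=False)
        common = surr.common_correlated_probes(per_tissue)
        save(
            pd.DataFrame({"probe_id": sorted(common)}),
            "common_correlated_probes.tsv",
            index=False,
        )
        sims = []
        for t in eye_tissues:
            sim_tab = surr.paired_similarity(beta, sheet, "blood", t, acfg)
            sims.append(
                {
                    "tissue": t,
                    "n_similar": int(sim_tab["similar"].sum()),
                    "n_probes": len(sim_tab),
                }
            )
            save(sim_tab, f"paired_similarity_blood_{t}.tsv")
        save(pd.DataFrame(sims), "paired_similarity_summary.tsv", index=False)
        run.results["surrogate"] = {
            "variable": variable,
            "per_tissue": per_tissue,
            "common": common,
            "null_stats": null_stats,
        }

    elif stage == "structure":
        beta, sheet = state["beta"], state["sheet"]
        section = cfg.get("structure") or {}
        alpha = float(section.get("alpha", 0.05))
        mvals = beta_to_m(beta)
        pca = struct.run_pca(mvals)
        scree = pd.DataFrame(
            {
                "component": np.arange(1, pca.n_components + 1),
                "variance_explained_pct": pca.variance_explained,
            }
        )
        save(scree, "pca_scree.tsv", index=False)
        save(pca.scores, "pca_scores.tsv")
        assoc = struct.pc_trait_association(pca, sheet)
        save(assoc, "pc_trait_association.tsv", index=False)
        exclusive = struct.individual_exclusive_components(assoc, alpha=alpha)
        probes_by_pc = {}
        for comp in exclusive:
            probes_by_pc[comp] = struct.pc_associated_probes(mvals, pca, comp, acfg)
        pc_rows = [
            {"component": c, "probe_id": p}
            for c, ps in probes_by_pc.items()
            for p in ps
        ]
        save(
            pd.DataFrame(pc_rows, columns=["component", "probe_id"]),
            "individual_pc_probes.tsv",
            index=False,
        )
        tissue_spec = struct.tissue_specific_probes(mvals, sheet, acfg)
        save(tissue_spec, "tissue_specific_probes.tsv")
        run.results["structure"] = {
            "pca": pca,
            "assoc": assoc,
            "exclusive": exclusive,
            "probes_by_pc": probes_by_pc,
            "tissue_specific": tissue_spec,
        }

    elif stage == "enrich":
        beta, ann = state["beta"], state["ann"]
        background = set(beta.probe_ids)
        subsets: dict[str, set] = {}
        surr_res = run.results.get("surrogate")
        if surr_res:
            subsets["blood_variable"] = set(surr_res["variable"].probe_ids)
            for t, df in surr_res["per_tissue"].items():
                subsets[f"correlated_{t}"] = set(df.index[df["selected"]])
            subsets["common_correlated"] = set(surr_res["common"])
        struct_res = run.results.get("structure")
        if struct_res:
            for comp, ps in struct_res["probes_by_pc"].items():
                subsets[f"individual_pc{comp}"] = set(ps)
        tables = []
        for name, probes in subsets.items():
            if not probes:
                continue
            table = enr.enrichment_test(probes, background, ann)
            table.insert(0, "subset", name)
            tables.append(table)
        all_dist = enr.category_distribution(background, ann)
        all_dist.insert(0, "subset", "all_probes")
        save(all_dist, "category_distribution_all.tsv", index=False)
        if tables:
            save(pd.concat(tables, ignore_index=True), "enrichment.tsv", index=False)
        run.results["enrich"] = tables

    run.outputs[stage] = outputs
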