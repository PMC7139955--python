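"""Pipeline orchestration: simulate -> preprocess -> cluster -> score ->
associate -> report, driven by a YAML config, with a hash-chained run
manifest and a blinding guard.

Signature derivation (clustering, scoring) is blinded to outcome: those
stages read the expression matrix and the outcome-free sample
annotation table only, and the config validator rejects any attempt to
hand them the clinical table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import io as iio
from . import preprocess as pp
from . import scoring as sc
from . import survival as sv
from .matrix import LOG2
from .simulate import ModuleSpec, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: keys that would leak outcome data into blinded (derivation) stages
_BLINDED_STAGES = ("cluster", "score")
_FORBIDDEN_KEYS = {"clinical", "survival", "outcome", "clinical_path"}

_STAGE_ORDER = ("simulate", "preprocess", "cluster", "score", "associate", "report")


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from the global seed and the stage name, so stages
    are individually re-runnable with stable streams."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_config(config: dict) -> None:
    if "seed" not in config:
        raise ValueError("config must set a global 'seed'")
    for stage in _BLINDED_STAGES:
        for key in config.get(stage, {}) or {}:
            if key in _FORBIDDEN_KEYS:
                raise ValueError(
                    f"blinding violation: stage {stage!r} must not reference "
                    f"outcome data (found key {key!r})"
                )
    unknown = set(config) - set(_STAGE_ORDER) - {"seed", "out_dir", "schema_version", "cohort"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    validate_config(config)
    return config


def _record(
    manifest: dict,
    stage: str,
    params: dict,
    inputs: list[Path],
    outputs: list[Path],
    seed: int,
    warnings: list[str] | None = None,
) -> None:
    manifest["stages"].append(
        {
            "stage": stage,
            "seed": seed,
            "params": params,
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": {str(p): _sha256(p) for p in outputs},
            "warnings": warnings or [],
        }
    )


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    Each stage writes its outputs under ``out_dir`` and appends a
    manifest entry (parameters, per-stage seed, input/output SHA-256
    hashes, warnings).  A stage failure aborts the run with the failing
    stage named; outputs of completed stages are retained.
    """
    validate_config(config)
    out = Path(out_dir or config.get("out_dir", "immunosig_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "out_dir": str(out),
        "stages": [],
    }

    state: dict = {}
    for stage in _STAGE_ORDER:
        conf = config.get(stage)
        if conf is None or conf.get("enabled", True) is False:
            continue
        try:
            _STAGE_FUNCS[stage](conf, state, out, manifest, seed)
        except Exception as err:
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(conf: dict, state: dict, out: Path, manifest: dict, seed: int) -> None:
    sseed = derive_stage_seed(seed, "simulate")
    kwargs = {
        k: v
        for k, v in conf.items()
        if k not in ("enabled", "modules") and k in SimulationConfig.__dataclass_fields__
    }
    if "modules" in conf:
        kwargs["modules"] = [ModuleSpec(**m) for m in conf["modules"]]
    sim = SimulationConfig(seed=sseed, **kwargs)
    cohort = simulate_cohort(sim)
    expr_path = out / "expression.tsv"
    iio.write_expression_tsv(cohort.expression, expr_path)
    samples_path = out / "samples.tsv"
    iio.write_clinical_tsv(cohort.expression.sample_annotations, samples_path)
    clin_path = out / "clinical.tsv"
    iio.write_clinical_tsv(cohort.clinical, clin_path)
    truth = cohort.truth
    truth_json = {
        "membership": truth["membership"],
        "active": {k: bool(v) for k, v in truth["active"].items()},
        "betas": truth["betas"],
        "raw_scores": truth["raw_scores"].round(10).to_dict(orient="index"),
        "z_scores": truth["z_scores"].round(10).to_dict(orient="index"),
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth_json, indent=2))
    gmt_path = out / "signatures.gmt"
    iio.write_gmt(
        {
            m.name: {"description": "simulated module", "genes": m.gene_names()}
            for m in sim.modules
        },
        gmt_path,
    )
    state["expression"] = cohort.expression
    state["clinical"] = cohort.clinical
    state["truth"] = truth
    _record(
        manifest,
        "simulate",
        {k: str(v) for k, v in conf.items() if k != "enabled"},
        [],
        [expr_path, samples_path, clin_path, truth_path, gmt_path],
        sseed,
    )


def _stage_preprocess(conf: dict, state: dict, out: Path, manifest: dict, seed: int) -> None:
    sseed = derive_stage_seed(seed, "preprocess")
    inputs: list[Path] = []
    if "expression" in conf:
        m = iio.read_expression_tsv(conf["expression"])
        inputs.append(Path(conf["expression"]))
    else:
        m = state["expression"]
        inputs.append(out / "expression.tsv")
    if conf.get("probe_map"):
        pmap = iio.read_probe_map(conf["probe_map"])
        m, _ = pp.collapse_probes(m, pmap)
        inputs.append(Path(conf["probe_map"]))
    if conf.get("cap"):
        ann = m.sample_annotations
        labels = (
            list(ann["cancer_type"]) if ann is not None and "cancer_type" in ann
            else ["all"] * m.n_samples
        )
        keep = pp.stratified_sample(m.sample_ids, labels, cap=int(conf["cap"]), seed=sseed)
        m = m.subset_samples(keep)
    if conf.get("uq", True):
        m, _ = pp.upper_quartile_normalize(
            m,
            detection_count=conf.get("detection_count", 1.0),
            detection_fraction=conf.get("detection_fraction", 0.75),
        )
    if conf.get("log2", True):
        m = pp.log2_transform(m, offset=conf.get("offset", 1.0))
    log2_path = out / "expression_log2.tsv"
    iio.write_expression_tsv(m, log2_path)
    state["log2"] = m
    centered = pp.center_genes(m) if conf.get("center", True) else m
    centered_path = out / "expression_centered.tsv"
    iio.write_expression_tsv(centered, centered_path)
    state["centered"] = centered
    _record(
        manifest,
        "preprocess",
        {k: str(v) for k, v in conf.items() if k != "enabled"},
        inputs,
        [log2_path, centered_path],
        sseed,
    )


def _stage_cluster(conf: dict, state: dict, out: Path, manifest: dict, seed: int) -> None:
    sseed = derive_stage_seed(seed, "cluster")
    m = state["centered"]
    linkage = conf.get("linkage", "centroid")
    d_genes = cl.hierarchical_cluster(m, axis="genes", linkage=linkage)
    nwk_genes = out / "dendrogram_genes.nwk"
    nwk_genes.write_text(cl.to_newick(d_genes))
    immunome = (
        cl.ImmunomeModel.from_gmt(conf["immunome"])
        if conf.get("immunome")
        else cl.ImmunomeModel.default()
    )
    modules, unassigned = cl.extract_modules(
        d_genes,
        height=conf.get("cut_h"),
        k=conf.get("cut_k"),
        min_size=conf.get("min_size", 2),
        matrix=m,
        immunome=immunome,
    )
    mod_path = out / "modules.gmt"
    iio.write_gmt(
        {
            mod.name: {
                "description": ";".join(mod.dominant_classes) or "unannotated",
                "genes": mod.genes,
            }
            for mod in modules
        },
        mod_path,
    )
    classes = conf.get("classes_of_interest")
    if classes:
        focus = cl.select_focus_set(modules, immunome, classes)
    else:
        focus = sorted({g for mod in modules for g in mod.genes})
    focus_path = out / "focus_set.txt"
    focus_path.write_text("\n".join(focus) + "\n")
    d_samples = cl.hierarchical_cluster(
        state["centered"].subset_genes([g for g in focus if g in m.values.index]),
        axis="samples",
        linkage=linkage,
    )
    nwk_samples = out / "dendrogram_samples.nwk"
    nwk_samples.write_text(cl.to_newick(d_samples))
    partition = cl.partition_samples(d_samples, state["log2"], focus)
    part_path = out / "partition.tsv"
    partition.rename("immune_group").to_frame().to_csv(part_path, sep="\t")
    state["modules"] = modules
    state["focus"] = focus
    state["partition"] = partition
    _record(
        manifest,
        "cluster",
        {k: str(v) for k, v in conf.items() if k != "enabled"},
        [out / "expression_centered.tsv"],
        [nwk_genes, mod_path, focus_path, nwk_samples, part_path],
        sseed,
        warnings=d_genes.warnings + d_samples.warnings,
    )


def _stage_score(conf: dict, state: dict, out: Path, manifest: dict, seed: int) -> None:
    sseed = derive_stage_seed(seed, "score")
    src = conf.get("signatures", "default")
    if src == "default":
        sigs = sc.load_default_signatures()
        inputs = [out / "expression_log2.tsv"]
    else:
        raw = iio.read_gmt(src)
        sigs = {
            name: sc.SignatureDefinition(name, rec["genes"], rec["weights"])
            for name, rec in raw.items()
        }
        inputs = [out / "expression_log2.tsv", Path(src)]
    ratios = [tuple(r) for r in conf.get("ratios", [["TCT", "M2TAM"]])]
    scores = sc.score_signatures(
        state["log2"], sigs, ratios=ratios, max_missing=conf.get("max_missing", 0.10)
    )
    frame = sc.scores_frame(scores)
    scores_path = out / "scores.tsv"
    frame.to_csv(scores_path, sep="\t")
    state["scores"] = frame
    params_path = out / "standardization.json"
    params_path.write_text(
        json.dumps(
            {name: {"q15": s.q15, "q85": s.q85} for name, s in scores.items()},
            indent=2,
        )
    )
    _record(
        manifest,
        "score",
        {k: str(v) for k, v in conf.items() if k != "enabled"},
        inputs,
        [scores_path, params_path],
        sseed,
    )


def _stage_associate(conf: dict, state: dict, out: Path, manifest: dict, seed: int) -> None:
    sseed = derive_stage_seed(seed, "associate")
    if "clinical" in conf:
        clinical = iio.read_clinical_tsv(conf["clinical"])
        inputs = [Path(conf["clinical"])]
    else:
        clinical = state["clinical"]
        inputs = [out / "clinical.tsv"]
    scores = state.get("scores")
    if scores is None and conf.get("scores"):
        scores = pd.read_csv(conf["scores"], sep="\t", index_col=0)
    zcols = [c for c in (scores.columns if scores is not None else []) if c.startswith("Z_")]
    table = clinical.drop(columns=[c for c in clinical.columns if c.startswith("Z_")])
    if scores is not None:
        table = table.join(scores[zcols], how="inner")
    signatures = conf.get("signatures") or [c[2:] for c in zcols]
    covariates = tuple(conf.get("covariates", ["age", "stage", "cytoreduction"]))
    ties = conf.get("ties", "breslow")
    results = {}
    for sig in signatures:
        model = sv.build_model(
            table,
            sig,
            base_covariates=covariates,
            ties=ties,
        )
        results[sig] = {
            "final": model.final.to_dict(),
            "full": model.full.to_dict(),
            "cytoreduction_dropped": model.cytoreduction_dropped,
            "cytoreduction_p": model.cytoreduction_p,
        }
    models_path = out / "models.json"
    models_path.write_text(json.dumps(results, indent=2))
    state["models"] = results
    if conf.get("km"):
        sig = conf["km"]
        groups = pd.Series(
            np.where(table[f"Z_{sig}"] > table[f"Z_{sig}"].median(), "High", "Low"),
            index=table.index,
        )
        curves, two_group = sv.kaplan_meier(table, groups)
        sv.plot_km(curves, str(out / "km.png"), title=sig)
    _record(
        manifest,
        "associate",
        {k: str(v) for k, v in conf.items() if k != "enabled"},
        inputs + [out / "scores.tsv"],
        [models_path],
        sseed,
    )


def _stage_report(conf: dict, state: dict, out: Path, manifest: dict, seed: int) -> None:
    sseed = derive_stage_seed(seed, "report")
    models = state.get("models")
    if not models:
        raise ValueError("no model results available to report")
    text = render_report(models)
    report_path = out / "report.md"
    report_path.write_text(text)
    _record(manifest, "report", {}, [out / "models.json"], [report_path], sseed)


def render_report(models: dict) -> str:
    """Markdown summary shaped like a multivariable-model results table:
    one block per signature with HR, CI and p per covariate."""
    if not models:
        raise ValueError("empty model results")
    lines = ["# Multivariable Cox PH model results", ""]
    for sig, rec in models.items():
        final = rec["final"]
        lines.append(f"## {sig} (n = {final['n']}, events = {final['n_events']}, ties = {final['ties']})")
        lines.append("")
        lines.append("| term | HR | 95% CI | p |")
        lines.append("|---|---|---|---|")
        for name, t in final["terms"].items():
            lines.append(
                f"| {name} | {t['hr']:.3f} | ({t['ci'][0]:.3f}, {t['ci'][1]:.3f}) | {t['p']:.3g} |"
            )
        for name, b in final.get("blocks", {}).items():
            lines.append(f"| {name} (joint) |  |  | {b['p']:.3g} |")
        if rec.get("cytoreduction_dropped"):
            lines.append("")
            lines.append(
                f"cytoreduction: not included (p > 0.10; joint Wald p = "
                f"{rec['cytoreduction_p']:.3g})"
            )
        lines.append("")
    return "\n".join(lines)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "cluster": _stage_cluster,
    "score": _stage_score,
    "associate": _stage_associate,
    "report": _stage_report,
}
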