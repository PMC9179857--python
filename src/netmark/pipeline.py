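"""End-to-end orchestration: simulate/load → DE → module → features → model → evaluate.

Runs the eight stages of the biomarker-prediction workflow, writes every
intermediate artifact as plain text under the run directory, and records a
manifest (config hash, derived seeds, per-stage counts, artifact paths).
Re-running with an identical configuration reproduces byte-identical TSV
outputs — every random stage derives its seed from the single top-level seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from . import __version__
from .active_module import (
    build_ccs_ppin,
    filter_by_confidence,
    greedy_module_search,
    zmap_from_table,
)
from .diffexpr import annotate_degs, differential_expression, filter_degs
from .errors import ValidationError
from .evaluation import (
    combine_biomarkers_logistic,
    evaluate_recovery,
    single_gene_diagnostics,
)
from .kernels import KernelSpec
from .model import (
    LabeledSet,
    compare_kernels,
    fit_svm,
    predict_candidates,
    score_nodes,
    select_features,
    selected_or_all,
)
from .synthetic import SyntheticConfig, simulate
from .topology import compute_features

__all__ = ["default_config", "load_config", "config_hash", "run_pipeline"]

STAGES = (
    "simulate",
    "diffexpr",
    "module",
    "features",
    "select",
    "train",
    "predict",
    "evaluate",
)


def default_config() -> dict:
    """The fully-specified defaults shipped with the package."""
    text = resources.files("netmark").joinpath("config/defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_update(base: dict, extra: dict) -> dict:
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a user YAML file and programmatic overrides."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(config, user)
    if overrides:
        _deep_update(config, copy.deepcopy(overrides))
    return config


def config_hash(config: dict) -> str:
    """Digest of the scientific configuration (output location excluded)."""
    scrubbed = {k: v for k, v in config.items() if k != "out_dir"}
    canon = yaml.safe_dump(scrubbed, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    names = ("simulate", "negatives", "split", "tree")
    return {n: int(s) for n, s in zip(names, rng.integers(2**31 - 1, size=len(names)))}


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config = copy.deepcopy(config)
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "netmark_run"))
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(config["seed"]))
    manifest: dict = {
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "seeds": seeds,
        "stages": [],
        "artifacts": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"].append({"name": stage, "status": "completed", **counts})

    def artifact(name: str, path: Path) -> Path:
        manifest["artifacts"][name] = str(path)
        return path

    current = "simulate"
    try:
        # ---- stage 1: simulate or load inputs ------------------------------
        truth = None
        expression = sample_labels = None
        if config["simulate"]["enabled"]:
            sim_cfg = SyntheticConfig(
                n_nodes=config["simulate"]["n_nodes"],
                attachment_m=config["simulate"]["attachment_m"],
                module_size=config["simulate"]["module_size"],
                signal_mean=config["simulate"]["signal_mean"],
                n_biomarkers=config["simulate"]["n_biomarkers"],
                n_cases=config["simulate"]["n_cases"],
                n_controls=config["simulate"]["n_controls"],
                noise_sd=config["simulate"]["noise_sd"],
                seed=seeds["simulate"],
                biomarker_placement=config["simulate"]["biomarker_placement"],
                biomarker_auc_target=config["simulate"]["biomarker_auc_target"],
                module_auc_target=config["simulate"]["module_auc_target"],
            )
            sim = simulate(sim_cfg)
            network, de_table, truth = sim.network, sim.de_table, sim.truth
            expression, sample_labels = sim.expression, sim.sample_labels
            nio.write_network(network, artifact("network", out / "network.tsv"))
            nio.write_de_table(de_table, artifact("de_table", out / "de.tsv"))
            nio.write_expression(expression, artifact("expression", out / "expression.tsv"))
            nio.write_labels(sample_labels, artifact("labels", out / "labels.tsv"))
            nio.write_truth(truth, artifact("truth", out / "truth.json"))
            known_biomarkers = sorted(truth.biomarker_nodes)
        else:
            paths = config["inputs"]
            if not paths.get("network"):
                raise ValidationError("simulate disabled and no inputs.network given")
            network = nio.read_network(paths["network"])
            de_table = nio.read_de_table(paths["de_table"]) if paths.get("de_table") else None
            if paths.get("expression"):
                expression = nio.read_expression(paths["expression"])
                sample_labels = nio.read_labels(paths["labels"])
            if de_table is None:
                if expression is None:
                    raise ValidationError("need inputs.de_table or inputs.expression")
                de_table = differential_expression(expression, sample_labels)
            if paths.get("truth"):
                truth = nio.read_truth(paths["truth"])
            if paths.get("biomarkers"):
                known_biomarkers = nio.read_gene_list(paths["biomarkers"])
            elif truth is not None:
                known_biomarkers = sorted(truth.biomarker_nodes)
            else:
                raise ValidationError(
                    "need inputs.biomarkers (or truth) to label training nodes"
                )
        record("simulate", nodes=network.number_of_nodes(),
               edges=network.number_of_edges(), genes=len(de_table))

        # ---- stage 2: DEG filter ------------------------------------------
        current = "diffexpr"
        de_cfg = config["diffexpr"]
        de_table = annotate_degs(de_table, de_cfg["p_threshold"], de_cfg["lfc_threshold"])
        degs = filter_degs(de_table, de_cfg["p_threshold"], de_cfg["lfc_threshold"])
        nio.write_de_table(de_table, artifact("de_annotated", out / "de_annotated.tsv"))
        record("diffexpr", degs=len(degs))

        # ---- stage 3: active module + disease subnetwork -------------------
        current = "module"
        net = filter_by_confidence(network, config["network"]["min_confidence"])
        zmap = zmap_from_table(de_table)
        mod_cfg = config["module"]
        if mod_cfg["enabled"]:
            module = greedy_module_search(
                net,
                zmap,
                iterations=mod_cfg["iterations"],
                max_size=mod_cfg["max_size"],
                normalization=mod_cfg["normalization"],
            )
            module_nodes = sorted(module.nodes)
            module_score = module.score
        else:
            if not mod_cfg.get("membership"):
                raise ValidationError("module disabled and no module.membership given")
            member = pd.read_csv(mod_cfg["membership"], sep="\t")
            module_nodes = sorted(member["node"].astype(str))
            from .active_module import aggregate_score

            module_score = aggregate_score(
                zmap.reindex(zmap.index.union(module_nodes), fill_value=0.0),
                module_nodes,
                mod_cfg["normalization"],
            )
        pd.DataFrame({"node": module_nodes}).to_csv(
            artifact("module", out / "module.tsv"), sep="\t", index=False
        )
        ccs = build_ccs_ppin(net, zmap, mod_cfg["z_threshold"])
        nio.write_network(ccs, artifact("ccs_edges", out / "ccs_edges.tsv"))
        nio.write_graphml(ccs, artifact("ccs_graphml", out / "ccs.graphml"))
        record("module", module_size=len(module_nodes),
               module_score=float(module_score),
               ccs_nodes=ccs.number_of_nodes(), ccs_edges=ccs.number_of_edges())

        # ---- stage 4: topology features ------------------------------------
        current = "features"
        features = compute_features(ccs)
        nio.write_features(features, artifact("features", out / "features.tsv"))
        record("features", nodes=len(features), columns=features.shape[1])

        # ---- stage 5: labeled set + tree feature selection -----------------
        current = "select"
        ccs_nodes = set(features.index)
        positives = sorted(set(known_biomarkers) & ccs_nodes)
        non_de_pool = sorted(ccs_nodes - degs - set(known_biomarkers))
        if len(positives) < 4:
            raise ValidationError(
                f"only {len(positives)} known biomarkers inside the subnetwork; "
                "cannot form train/test partitions"
            )
        rng = np.random.default_rng(seeds["negatives"])
        n_neg = min(len(positives), len(non_de_pool))
        negatives = sorted(
            rng.choice(non_de_pool, size=n_neg, replace=False).tolist()
        )
        labeled = LabeledSet.from_nodes(
            positives,
            negatives,
            train_fraction=config["train"]["train_fraction"],
            seed=seeds["split"],
        )
        labeled.frame.to_csv(artifact("node_labels", out / "node_labels.tsv"), sep="\t")
        sel_cfg = config["select"]
        tree = select_features(
            features,
            labeled,
            min_split=sel_cfg["min_split"],
            complexity=sel_cfg["complexity"],
            flavor=sel_cfg["flavor"],
            seed=seeds["tree"],
        )
        selected = selected_or_all(tree)
        with open(artifact("selected_features", out / "selected_features.json"), "w") as fh:
            json.dump({"selected": tree.selected_features, "used": selected}, fh, indent=1)
        record("select", positives=len(positives), negatives=len(negatives),
               selected=len(tree.selected_features), used=len(selected))

        # ---- stage 6: kernel SVM ------------------------------------------
        current = "train"
        tr_cfg = config["train"]
        spec = KernelSpec(
            name=tr_cfg["kernel"], sigma=tr_cfg["sigma"], degree=tr_cfg["degree"],
            nu=tr_cfg["nu"], scale=tr_cfg["scale"], offset=tr_cfg["offset"],
        )
        kernel_table = None
        if tr_cfg["compare_kernels"]:
            specs = [
                KernelSpec(name=n, sigma=tr_cfg["sigma"], degree=tr_cfg["degree"],
                           nu=tr_cfg["nu"], scale=tr_cfg["scale"], offset=tr_cfg["offset"])
                for n in ("linear", "polynomial", "rbf", "laplacian",
                          "tanh", "bessel", "anova_rbf", "spline")
            ]
            kernel_table = compare_kernels(
                features, labeled, specs, C=tr_cfg["C"], feature_names=selected
            )
            kernel_table.to_csv(artifact("kernel_auc", out / "kernel_auc.tsv"),
                                sep="\t", index=False, float_format="%.10g")
        svm = fit_svm(features, labeled, spec, C=tr_cfg["C"], feature_names=selected)
        svm.save(artifact("model", out / "model.json"))
        record("train", kernel=spec.name,
               support_vectors=int(len(svm.support_indices)),
               kernels_compared=0 if kernel_table is None else len(kernel_table))

        # ---- stage 7: candidate prediction ---------------------------------
        current = "predict"
        universe = config["predict"].get("universe", "ccs")
        if universe == "ccs":
            scored_universe = features
        elif universe == "degs":
            scored_universe = features.loc[sorted(ccs_nodes & degs)]
        else:
            raise ValidationError("predict.universe must be 'ccs' or 'degs'")
        points = score_nodes(svm, scored_universe)
        points.to_csv(artifact("points", out / "points.tsv"), sep="\t",
                      float_format="%.10g")
        train_positives = {
            n for n in labeled.nodes("train")
            if labeled.frame.at[n, "label"] == "biomarker"
        }
        candidates = predict_candidates(
            svm, scored_universe, cutoff=config["predict"]["cutoff"],
            exclude=train_positives,
        )
        candidates.to_csv(artifact("candidates", out / "candidates.tsv"), sep="\t",
                          float_format="%.10g")
        record("predict", scored=len(points), candidates=len(candidates),
               cutoff=config["predict"]["cutoff"])

        # ---- stage 8: evaluation -------------------------------------------
        current = "evaluate"
        metrics: dict = {}
        if truth is not None and truth.biomarker_nodes:
            metrics["recovery"] = evaluate_recovery(
                points, truth, cutoff=config["predict"]["cutoff"]
            )
        if expression is not None:
            top = list(points.index[: config["evaluate"]["top_genes"]])
            singles = {}
            for gene in top:
                if gene in expression.index:
                    roc = single_gene_diagnostics(expression, sample_labels, gene)
                    singles[gene] = {"auc": roc.auc, "orientation": roc.orientation}
            metrics["single_gene_auc"] = singles
            if config["evaluate"]["panel"]:
                panel_genes = list(candidates.index) or top
                panel_genes = [g for g in panel_genes if g in expression.index]
                if panel_genes:
                    panel = combine_biomarkers_logistic(
                        expression, sample_labels, panel_genes
                    )
                    metrics["panel"] = {
                        "genes": panel.genes,
                        "auc": panel.roc.auc,
                        "orientation": panel.roc.orientation,
                        "ridge": panel.ridge,
                    }
                    panel.roc.frame().to_csv(
                        artifact("panel_roc", out / "panel_roc.tsv"),
                        sep="\t", index=False, float_format="%.10g",
                    )
        with open(artifact("metrics", out / "metrics.json"), "w") as fh:
            json.dump(metrics, fh, indent=1, default=float)
        record("evaluate", metrics=len(metrics))
    except Exception as exc:
        manifest["stages"].append({"name": current, "status": "failed",
                                   "error": f"{type(exc).__name__}: {exc}"})
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
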