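"""End-to-end orchestration: simulate -> preprocess -> refine -> stratify ->
map -> dge -> enrich -> network, with a manifest of outputs.

Each stage writes flat files to the output directory so any stage can be
inspected or rerun; the manifest records stage inputs/outputs, the effective
config (and its hash), the seed, timestamps and warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, dge, enrich, preprocess, refine, stratify
from .io import RunConfig, write_expression, write_network
from .synthetic import CohortSpec, simulate_cohort


def _config_hash(config: RunConfig, spec: CohortSpec) -> str:
    blob = json.dumps(
        {"config": dataclasses.asdict(config), "spec": dataclasses.asdict(spec)},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    spec: CohortSpec,
    out_dir: str | Path,
    covariate_names: tuple[str, ...] = ("sex", "age_death", "batch"),
) -> dict:
    """Run the full synthetic-cohort pipeline; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "cohort_spec": dataclasses.asdict(spec),
        "config_hash": _config_hash(config, spec),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "warnings": [],
    }

    def stage(name: str, outputs: dict[str, Path]) -> None:
        manifest["stages"].append(
            {"name": name, "outputs": {k: str(v) for k, v in outputs.items()}}
        )

    # --- simulate ---------------------------------------------------------
    geno, _, expr, modules, cov, truth = simulate_cohort(spec)
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    stage("simulate", {"truth": truth_path})

    # --- preprocess -------------------------------------------------------
    resid = preprocess.residualize(expr, cov, list(covariate_names))
    expr_std = preprocess.standardize(resid)
    resid_path = out / "expression_residualized.tsv"
    write_expression(resid, resid_path)
    stage("preprocess", {"residualized": resid_path})

    # --- refine -----------------------------------------------------------
    submodules, dropped = refine.refine_all_modules(expr_std, modules, config)
    if not submodules:
        manifest["warnings"].append("no submodules recovered")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest
    members = pd.DataFrame(
        [
            (g, sub.label.rsplit("_", 1)[0], sub.label, float(sub.kme[g]))
            for sub in submodules
            for g in sorted(sub.genes)
        ],
        columns=["gene_id", "module", "submodule", "kME"],
    )
    members_path = out / "submodule_members.tsv"
    members.to_csv(members_path, sep="\t", index=False)
    E = refine.eigengene_matrix(expr_std, submodules)
    eig_path = out / "eigengenes.tsv"
    E.to_csv(eig_path, sep="\t")
    stage("refine", {"members": members_path, "eigengenes": eig_path})

    # --- stratify ---------------------------------------------------------
    cases = cov.index[cov["diagnosis"] == "CASE"].tolist()
    model = stratify.fit_subtypes(
        E.loc[cases],
        k_range=range(config.k_min, config.k_max + 1),
        seed=config.seed,
    )
    spec_traits = stratify.specificity_metric(E, model)
    labels_path = out / "subtype_labels.tsv"
    model.case_labels.rename_axis("sample_id").to_csv(labels_path, sep="\t")
    spec_path = out / "specificity_traits.tsv"
    spec_traits.to_csv(spec_path, sep="\t", index_label="sample_id")
    balance = stratify.covariate_balance(model, cov, ["sex", "batch"], ["age_death"])
    balance_path = out / "covariate_balance.tsv"
    balance.to_csv(balance_path, sep="\t", index=False)
    stage("stratify", {"labels": labels_path, "specificity": spec_path,
                       "balance": balance_path})

    # --- map --------------------------------------------------------------
    K = assoc.kinship(geno, method=config.kinship_method)
    n = geno.n_samples
    X = np.ones((n, 1))
    results = []
    lambdas = {}
    traits = {f"eigengene:{c}": E[c].to_numpy() for c in E.columns}
    traits.update(
        {f"specificity:{c}": spec_traits[c].to_numpy() for c in spec_traits.columns}
    )
    for tid, y in traits.items():
        null = assoc.fit_null(y, X, K)
        res = assoc.scan(y, X, K, geno, null, trait_id=tid)
        lambdas[tid] = res.attrs["lambda_gc"]
        results.append(res)
    all_results = pd.concat(results, ignore_index=True)
    assoc_path = out / "associations.tsv"
    all_results.to_csv(assoc_path, sep="\t", index=False)
    lambda_path = out / "lambda_gc.tsv"
    pd.Series(lambdas, name="lambda_gc").rename_axis("trait_id").to_csv(
        lambda_path, sep="\t"
    )
    try:
        hits = assoc.classify_hits(
            all_results, config.suggestive_p, config.significant_p
        )
    except ValueError:
        hits = all_results.iloc[0:0].assign(label=pd.Series(dtype=str))
    hits = assoc.clump_loci(hits, config.clump_window_bp) if len(hits) else hits
    hits_path = out / "hits.tsv"
    hits.to_csv(hits_path, sep="\t", index=False)
    stage("map", {"associations": assoc_path, "lambda": lambda_path,
                  "hits": hits_path})

    # --- dge --------------------------------------------------------------
    controls = dge.define_controls(cov, include_other=True)
    de_counts = {}
    for subtype in sorted(model.case_labels.unique()):
        members_s = model.case_labels.index[model.case_labels == subtype].tolist()
        if len(members_s) < 2:
            manifest["warnings"].append(f"subtype {subtype} too small for DE")
            continue
        table = dge.run_dge(resid, members_s, controls, config.de_fdr, config.de_lfc)
        path = out / f"dge_subtype_{subtype}.tsv"
        table.to_csv(path, sep="\t", index_label="gene_id")
        de_counts[str(subtype)] = {
            "up": table.attrs["n_up"], "down": table.attrs["n_down"]
        }
        stage(f"dge_subtype_{subtype}", {"table": path})

    # --- enrich (planted submodules as synthetic 'pathways') --------------
    universe = set(expr.index)
    queries = {sub.label: set(sub.genes) for sub in submodules}
    truth_sets = {}
    for g, (mod, idx) in truth.submodule_membership.items():
        if idx != "noise":
            truth_sets.setdefault(f"planted:{mod}_{idx}", set()).add(g)
    from .io import GeneSet

    gmt = [GeneSet(name, "planted submodule", frozenset(genes))
           for name, genes in sorted(truth_sets.items())]
    enr = enrich.enrich_all(queries, gmt, universe)
    enr_path = out / "enrichment.tsv"
    enr.to_csv(enr_path, sep="\t", index=False)
    stage("enrich", {"table": enr_path})

    # --- network ----------------------------------------------------------
    if len(hits):
        by_class = {
            "submodule": hits[hits["trait_id"].str.startswith("eigengene:")],
            "subtype": hits[hits["trait_id"].str.startswith("specificity:")],
        }
        by_class = {k: v for k, v in by_class.items() if len(v)}
        net = assoc.build_network(by_class)
    else:
        import networkx as nx

        net = nx.DiGraph()
    net_path = out / "phenotype_locus_network.graphml"
    write_network(net, net_path)
    stage("network", {"graphml": net_path})

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["summary"] = {
        "n_submodules": len(submodules),
        "k_star": model.k,
        "cluster_method": model.method,
        "subtype_sizes": model.case_labels.value_counts().to_dict(),
        "lambda_gc": lambdas,
        "n_hits": int(len(hits)),
        "n_loci": int(hits["locus_id"].nunique()) if len(hits) else 0,
        "de_counts": de_counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def report(manifest: dict) -> dict:
    """Condense a completed manifest into the headline numbers."""
    if "summary" not in manifest:
        return {"complete": False, "stages_run": [s["name"] for s in manifest["stages"]]}
    s = manifest["summary"]
    return {
        "complete": True,
        "n_submodules": s["n_submodules"],
        "k_star": s["k_star"],
        "cluster_method": s["cluster_method"],
        "subtype_sizes": s["subtype_sizes"],
        "median_lambda_gc": float(np.median(list(s["lambda_gc"].values()))),
        "n_hits": s["n_hits"],
        "n_loci": s["n_loci"],
        "de_counts": s["de_counts"],
    }
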