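"""End-to-end orchestration from a single validated configuration.

Stages: (optional) simulation -> QC -> normalization -> covariate regression
-> variable genes -> multi-resolution clustering -> resolution selection ->
conserved markers and annotation -> ko-vs-wt DEGs and uniqueness ->
expansion / positivity statistics -> gene-set enrichment -> spot
classification.  Every stage writes a TSV/JSON artifact and the run manifest
records parameters, seed and output hashes.
"""

from __future__ import annotations

import copy
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import markers as mk
from . import popstats, preprocess, restree, simulate
from .enrich import OverlapFilters, overlap_enrichment, read_gmt
from .spatial import SpotRules, classify_spots, proliferation_fisher, read_spots_tsv

__all__ = ["DEFAULT_CONFIG", "ConfigError", "validate_config", "run_pipeline"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "scvasc_out",
    "inputs": {
        "matrix": None, "barcodes": None, "features": None, "cell_meta": None,
        "spots": None, "panel": None, "gene_sets": None, "branches": None,
        "embedding": None,  # optional precomputed embedding TSV (cells x dims)
    },
    "simulate": None,  # SimulationConfig fields; used when no matrix input
    "qc": {"sd_k": 2.0, "mito_max": 0.05},
    "normalize": {"scale": 1e4},
    "cluster": {
        "n_pcs": 30, "neighbors_k": 20, "n_variable_genes": 2000,
        "resolutions": [0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    },
    "markers": {
        "min_fraction": 0.1, "p_adjust": "bonferroni",
        "annotate": {"logfc_min": 0.0, "p_max": 0.05, "share": 0.5},
        "unique_markers": {"logfc_min": 0.25, "p_max": 0.05},
        "unique_degs": {"logfc_min_abs": 0.2, "p_max": 0.05},
    },
    "expansion": {"level": 0.95, "exclude_groups": []},
    "positivity": {
        "gt_zero_markers": ["Mki67", "Plk1", "Mxd3", "Birc5", "Ube2c",
                            "Plaur", "Apln", "Mmrn2"],
        "gt_q1_markers": ["Bst1", "Peg3", "Procr", "Cd200"],
        "level": 0.95,
    },
    "enrich": {"p_max": 0.05, "q_max": 0.25, "q_direction": "le",
               "odds_min": 4.0, "min_overlap": 2,
               "logfc_min_abs": 0.3, "p_adj_max": 0.05},
    "spots": {
        "ec_genes": ["Cldn5", "Cdh5", "Pecam1"],
        "lesion_genes": ["Klf4", "Klf2", "Ly6a", "Thbd"],
        "tip_genes": ["Apln", "Plaur"],
        "proliferation_gene": "Mki67",
        "identity_threshold": 0.5, "proliferation_threshold": 1.0,
    },
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


def _merge(defaults: dict, override: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in (override or {}).items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            errors.append(f"unknown key: {where}")
            continue
        if isinstance(defaults[key], dict) and defaults[key] and not isinstance(value, dict):
            # sections must stay sections (except nullable leaves)
            if value is not None:
                errors.append(f"{where}: expected a mapping")
                continue
            out[key] = value
        elif isinstance(defaults[key], dict) and isinstance(value, dict) and key not in ("simulate",):
            out[key] = _merge(defaults[key], value, where, errors)
        else:
            out[key] = value
    return out


def validate_config(path_or_dict) -> dict:
    """Load, default-fill and validate a pipeline config; errors aggregate."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    config = _merge(DEFAULT_CONFIG, raw, "", errors)

    qc = config["qc"]
    if not 0 <= qc["mito_max"] <= 1:
        errors.append(f"qc.mito_max={qc['mito_max']} must be in [0, 1]")
    if qc["sd_k"] <= 0:
        errors.append("qc.sd_k must be positive")
    if config["normalize"]["scale"] <= 0:
        errors.append("normalize.scale must be positive")
    if not 0 < config["expansion"]["level"] < 1:
        errors.append("expansion.level must be in (0, 1)")
    res = config["cluster"]["resolutions"]
    if len(res) < 1 or any(r <= 0 for r in res):
        errors.append("cluster.resolutions must be positive")
    elif sorted(res) != list(res):
        warnings.warn("cluster.resolutions not ascending; sorted")
        config["cluster"]["resolutions"] = sorted(res)
    if errors:
        raise ConfigError(errors)
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index=True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: dict) -> dict:
    """Execute all configured stages; returns the run manifest."""
    config = validate_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"seed": seed, "parameters": config, "stages": {}, "outputs": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "completed"
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)

    stage = "input"
    try:
        inputs = config["inputs"]
        if inputs["matrix"] is not None:
            counts = preprocess.read_mtx_triplet(
                inputs["matrix"], inputs["barcodes"], inputs["features"],
                inputs["cell_meta"])
            truth = None
        elif config["simulate"] is not None:
            stage = "simulate"
            sim_kwargs = dict(config["simulate"])
            sim_kwargs.setdefault("seed", seed)
            sim_config = simulate.SimulationConfig(**sim_kwargs)
            counts, truth = simulate.simulate_cells(sim_config)
            simulate.write_cells_mtx(counts, truth, outdir / "simulated")
            manifest["stages"]["simulate"] = "completed"
        else:
            raise ValueError("no matrix input and no simulate section")

        stage = "qc"
        filtered, report = preprocess.qc_filter(
            counts, sd_k=config["qc"]["sd_k"], mito_max=config["qc"]["mito_max"])
        _write_tsv(report.per_cell, outdir / "qc_report.tsv")
        record("qc", outdir / "qc_report.tsv")

        stage = "normalize"
        norm = preprocess.lognormalize(filtered, scale=config["normalize"]["scale"])

        stage = "cluster"
        hvg = preprocess.variable_genes(
            norm, n_top=min(config["cluster"]["n_variable_genes"], norm.values.shape[1]))
        scaled = preprocess.regress_covariate(norm)
        hvg_idx = norm.genes.get_indexer(hvg)
        if inputs["embedding"] is not None:
            emb = pd.read_csv(inputs["embedding"], sep="\t", index_col=0)
            emb = emb.reindex(norm.cells).to_numpy()
        else:
            n_pcs = min(config["cluster"]["n_pcs"], len(hvg), norm.values.shape[0])
            emb = preprocess.pca_embed(scaled[:, hvg_idx], n_pcs=n_pcs, seed=seed)
        graph = preprocess.snn_graph(emb, neighbors_k=config["cluster"]["neighbors_k"])
        assignments = {
            float(r): pd.Series(
                preprocess.cluster_graph(graph, resolution=float(r), seed=seed),
                index=norm.cells)
            for r in config["cluster"]["resolutions"]
        }
        stage = "select_resolution"
        if len(assignments) >= 2:
            tree = restree.build_cluster_tree(assignments)
            region = restree.select_resolution(tree)
            selected = region.selected_resolution
            report_json = {
                "stable_regions": [list(r) for r in region.stable_regions],
                "overclustered_onset": region.overclustered_onset,
                "selected_resolution": selected,
            }
        else:
            selected = list(assignments)[0]
            report_json = {"selected_resolution": selected,
                           "note": "single resolution supplied"}
        clusters = assignments[selected]
        (outdir / "region_report.json").write_text(json.dumps(report_json, indent=2))
        cl_out = pd.DataFrame({r: s for r, s in assignments.items()})
        cl_out["selected"] = clusters
        _write_tsv(cl_out, outdir / "clusters.tsv")
        record("cluster", outdir / "clusters.tsv", outdir / "region_report.json")

        stage = "markers"
        marker_table = mk.conserved_markers(
            norm, clusters, min_fraction=config["markers"]["min_fraction"],
            p_adjust=config["markers"]["p_adjust"])
        _write_tsv(marker_table, outdir / "markers.tsv", index=False)
        record("markers", outdir / "markers.tsv")

        stage = "annotate"
        if inputs["panel"] is not None:
            panel = mk.read_key_gene_panel(inputs["panel"])
            ann = mk.annotate_clusters(
                marker_table, panel, all_genes=norm.genes,
                **config["markers"]["annotate"])
            _write_tsv(ann, outdir / "annotations.tsv", index=False)
            record("annotate", outdir / "annotations.tsv")
        else:
            manifest["stages"]["annotate"] = "skipped (no panel)"

        stage = "compare"
        degs, deg_summary = mk.deg_ko_vs_wt(
            norm, clusters, p_adjust=config["markers"]["p_adjust"])
        _write_tsv(degs, outdir / "degs.tsv", index=False)
        _write_tsv(deg_summary, outdir / "deg_summary.tsv", index=False)
        uniq_m = mk.unique_markers(marker_table, **config["markers"]["unique_markers"])
        uniq_d = mk.unique_degs(degs, **config["markers"]["unique_degs"])
        (outdir / "unique_markers.json").write_text(
            json.dumps({str(k): v for k, v in uniq_m.items()}, indent=2))
        (outdir / "unique_degs.json").write_text(
            json.dumps({str(k): v for k, v in uniq_d.items()}, indent=2))
        record("compare", outdir / "degs.tsv", outdir / "deg_summary.tsv",
               outdir / "unique_markers.json", outdir / "unique_degs.json")

        stage = "expand"
        grouping = clusters
        if inputs["branches"] is not None:
            grouping = popstats.load_branches(inputs["branches"]).reindex(norm.cells)
        genotype = norm.cell_meta["genotype"]
        tab = pd.crosstab(grouping, genotype)
        for g in config["expansion"]["exclude_groups"]:
            tab = tab.drop(index=g, errors="ignore")
        for gt in ("wt", "ko"):
            if gt not in tab:
                tab[gt] = 0
        expansion = popstats.expansion_fold(tab[["wt", "ko"]],
                                            level=config["expansion"]["level"])
        exp_out = expansion.per_group.copy()
        exp_out["ci_upper"] = expansion.ci_upper
        _write_tsv(exp_out, outdir / "expansion.tsv")
        record("expand", outdir / "expansion.tsv")

        stage = "positivity"
        pos_rows = []
        for gene in config["positivity"]["gt_zero_markers"]:
            if gene not in norm.genes:
                continue
            pos = popstats.positive_cells(norm, gene, popstats.PositivityRule("gt_zero"))
            per_gt, fold = popstats.positivity_fraction_fold(
                pos, grouping, genotype, level=config["positivity"]["level"])
            per_gt["gene"] = gene
            per_gt["rule"] = "gt_zero"
            pos_rows.append(per_gt)
        for gene in config["positivity"]["gt_q1_markers"]:
            if gene not in norm.genes:
                continue
            pos = popstats.positive_cells(norm, gene, popstats.PositivityRule("gt_q1"))
            per_gt, fold = popstats.positivity_fraction_fold(
                pos, grouping, genotype, level=config["positivity"]["level"])
            per_gt["gene"] = gene
            per_gt["rule"] = "gt_q1"
            pos_rows.append(per_gt)
        if pos_rows:
            _write_tsv(pd.concat(pos_rows, ignore_index=True),
                       outdir / "positivity.tsv", index=False)
            record("positivity", outdir / "positivity.tsv")
        else:
            manifest["stages"]["positivity"] = "skipped (no configured marker present)"

        stage = "enrich"
        if inputs["gene_sets"] is not None:
            collection = read_gmt(inputs["gene_sets"], universe=norm.genes)
            filters = OverlapFilters(
                p_max=config["enrich"]["p_max"], q_max=config["enrich"]["q_max"],
                q_direction=config["enrich"]["q_direction"],
                odds_min=config["enrich"]["odds_min"],
                min_overlap=config["enrich"]["min_overlap"])
            sig = degs[(degs["adj_p"] < config["enrich"]["p_adj_max"])
                       & (degs["logFC"].abs() >= config["enrich"]["logfc_min_abs"])]
            enr_rows = []
            for cluster, sub in sig.groupby("cluster"):
                for direction, genes in (("up", sub[sub["logFC"] > 0]["gene"]),
                                         ("down", sub[sub["logFC"] < 0]["gene"])):
                    if len(genes) == 0:
                        continue
                    res = overlap_enrichment(genes, collection, filters)
                    res.insert(0, "cluster", cluster)
                    res.insert(1, "direction", direction)
                    enr_rows.append(res)
            if enr_rows:
                _write_tsv(pd.concat(enr_rows, ignore_index=True),
                           outdir / "enrichment.tsv", index=False)
                record("enrich", outdir / "enrichment.tsv")
            else:
                manifest["stages"]["enrich"] = "skipped (no significant DEGs)"
        else:
            manifest["stages"]["enrich"] = "skipped (no gene sets)"

        stage = "spots"
        if inputs["spots"] is not None:
            spot_matrix = read_spots_tsv(inputs["spots"])
            sp_cfg = config["spots"]
            rules = SpotRules(
                ec_genes=tuple(sp_cfg["ec_genes"]),
                lesion_genes=tuple(sp_cfg["lesion_genes"]),
                tip_genes=tuple(sp_cfg["tip_genes"]),
                proliferation_gene=sp_cfg["proliferation_gene"],
                identity_threshold=sp_cfg["identity_threshold"],
                proliferation_threshold=sp_cfg["proliferation_threshold"],
                scale=config["normalize"]["scale"])
            flags = classify_spots(spot_matrix, rules)
            _write_tsv(flags, outdir / "spot_flags.tsv")
            try:
                table, p = proliferation_fisher(
                    flags, genotypes=spot_matrix.spot_meta["genotype"])
                (outdir / "spot_fisher.json").write_text(json.dumps(
                    {"table": table.tolist(), "p": p}, indent=2))
                record("spots", outdir / "spot_flags.tsv", outdir / "spot_fisher.json")
            except ValueError as exc:
                manifest["stages"]["spots"] = f"flags written; fisher skipped ({exc})"
                manifest["outputs"]["spot_flags.tsv"] = _sha256(outdir / "spot_flags.tsv")
        else:
            manifest["stages"]["spots"] = "skipped (no spot input)"
    except Exception as exc:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
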