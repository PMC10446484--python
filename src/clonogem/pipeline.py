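"""End-to-end pipeline: simulate/load -> qc -> cluster -> markers ->
clonotype -> regulon -> gem -> report.

One flat YAML config drives a run; every stage writes its tables through
:mod:`clonogem.io_formats` into a per-stage subdirectory of the output dir,
and a top-level run manifest records the config hash, seed, stage status and
entity counts (cells/genes/clones surviving each stage), so the filtering
chain is fully inspectable.  A stage failure leaves completed stage outputs
intact and names the failed stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import clonotypes as ct
from . import gems
from . import markers as mk
from . import qc as qcmod
from . import regulons as rg
from .errors import ClonogemError, ConfigError
from .io_formats import (GeneCellCounts, config_hash, contigs_to_frame,
                         read_10x_triplet, read_contigs, write_10x_triplet,
                         write_results)
from .simulate import (SimConfig, simulate_clonotypes, simulate_expression,
                       simulate_regulons)

ALL_STAGES = ("simulate", "qc", "cluster", "markers", "clonotype",
              "regulon", "gem", "report")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``simulate`` (generator parameters) or ``inputs``
    (paths to a 10x triplet dir + sample sheet + contig CSV) must be present;
    the global ``seed`` is mandatory and feeds every stochastic stage.
    """

    seed: int
    out_dir: str
    simulate: dict | None = None
    inputs: dict | None = None
    qc: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    clonotype: dict = field(default_factory=dict)
    regulon: dict = field(default_factory=dict)
    gem: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ALL_STAGES
    embedding: str = "pca"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of 'simulate' or 'inputs' must be configured")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ConfigError(f"unknown config keys {sorted(extra)}")
        raw = dict(raw)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}

    def semantic_dict(self) -> dict:
        """Config content that determines results (out_dir excluded, so two
        runs of the same analysis hash identically wherever they land)."""
        d = self.to_dict()
        d.pop("out_dir")
        return d


def _stage_dir(config: RunConfig, stage: str) -> Path:
    return Path(config.out_dir) / stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.semantic_dict())
    manifest: dict = {"config_hash": chash, "seed": int(config.seed),
                      "stages": {}, "log": []}
    state: dict = {}

    def log(msg: str) -> None:
        manifest["log"].append(msg)

    for stage in ALL_STAGES:
        if stage not in config.stages:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        try:
            runner = _STAGE_RUNNERS[stage]
            if stage == "report":
                # the report reads the manifest, so flush it first
                _write_manifest(out_dir, manifest)
            info = runner(config, state, log)
            manifest["stages"][stage] = {"status": "ok", **(info or {})}
        except ClonogemError:
            _write_manifest(out_dir, manifest, stage_failed=stage)
            raise
        except Exception as exc:  # propagate with the stage name attached
            _write_manifest(out_dir, manifest, stage_failed=stage)
            raise ClonogemError(f"stage {stage!r} failed: {exc}") from exc
    _write_manifest(out_dir, manifest)
    return manifest


def _write_manifest(out_dir: Path, manifest: dict,
                    stage_failed: str | None = None) -> None:
    manifest = dict(manifest)
    if stage_failed:
        manifest["stages"] = dict(manifest["stages"])
        manifest["stages"][stage_failed] = {"status": "failed"}
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, log) -> dict:
    d = _stage_dir(config, "simulate")
    if config.inputs is not None:
        counts = read_10x_triplet(
            config.inputs["tenx_dir"],
            pd.read_csv(config.inputs["sample_sheet"], sep=None,
                        engine="python"))
        state["counts_raw"] = counts
        state["contig_path"] = config.inputs.get("contigs")
        log(f"loaded {counts.n_genes} genes x {counts.n_cells} cells")
        return {"n_genes": counts.n_genes, "n_cells": counts.n_cells,
                "source": "inputs"}
    sim = SimConfig(**{**(config.simulate or {}), "seed": int(config.seed)})
    counts, truth = simulate_expression(sim)
    if sim.n_regulons > 0:
        counts, reg_truth = simulate_regulons(sim, counts,
                                              truth.cluster_assignments)
        truth.regulon_truth = reg_truth.regulon_truth
    contigs, clone_truth = simulate_clonotypes(
        sim, truth.cluster_assignments, truth.conditions)
    truth.clone_table = clone_truth.clone_table
    truth.clone_of_cell = clone_truth.clone_of_cell
    write_10x_triplet(counts, d / "tenx")
    d.mkdir(parents=True, exist_ok=True)
    contigs.to_csv(d / "filtered_contig_annotations.csv", index=False)
    with open(d / "ground_truth.json", "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
    state["counts_raw"] = counts
    state["contig_path"] = d / "filtered_contig_annotations.csv"
    state["truth"] = truth
    log(f"simulated {counts.n_genes} genes x {counts.n_cells} cells")
    return {"n_genes": counts.n_genes, "n_cells": counts.n_cells,
            "source": "simulate"}


def _stage_qc(config: RunConfig, state: dict, log) -> dict:
    counts = state["counts_raw"]
    thr = qcmod.QCThresholds(**config.qc)
    filtered = qcmod.filter_counts(counts, thr)
    state["counts"] = filtered
    summary = pd.DataFrame([{
        "genes_in": counts.n_genes, "cells_in": counts.n_cells,
        "genes_out": filtered.n_genes, "cells_out": filtered.n_cells,
    }])
    write_results({"qc_summary": summary}, _stage_dir(config, "qc"),
                  config=config.semantic_dict(), seed=config.seed)
    log(f"qc: {counts.n_genes}x{counts.n_cells} -> "
        f"{filtered.n_genes}x{filtered.n_cells}")
    return {"n_genes": filtered.n_genes, "n_cells": filtered.n_cells}


def _stage_cluster(config: RunConfig, state: dict, log) -> dict:
    counts = state["counts"]
    opts = dict(config.cluster)
    embed_method = opts.pop("embedding", config.embedding)
    ccfg_fields = {k: v for k, v in opts.items()
                   if k in cl.ClusterConfig.__dataclass_fields__}
    ccfg = cl.ClusterConfig(**{**ccfg_fields, "seed": int(config.seed)})
    normalized = qcmod.lognormalize(counts)
    hvg = qcmod.select_hvg(counts.matrix, min(ccfg.n_hvg, counts.n_genes))
    scaled = qcmod.scale_genes(normalized[hvg])
    n_pcs = min(ccfg.n_pcs, len(hvg), counts.n_cells - 1)
    scores, evar = cl.run_pca(scaled, n_pcs, seed=config.seed)
    labels = cl.snn_cluster(scores, ccfg)
    xy = cl.embed_2d(scores, method=embed_method, seed=int(config.seed))
    state.update(normalized=normalized, labels=labels, scores=scores, xy=xy)

    n_features = np.asarray((counts.matrix > 0).sum(axis=0)).ravel()
    annot = pd.DataFrame({
        "barcode": counts.barcodes,
        "cluster_id": labels,
        "condition": counts.conditions.to_numpy(),
        "n_features": n_features,
        "mito_fraction": qcmod.mito_fraction(counts),
        "embedding_x": xy[:, 0], "embedding_y": xy[:, 1],
    })
    comp = cl.composition(labels, counts.conditions.to_numpy())
    profiles = cl.cluster_mean_profiles(normalized, labels)
    tables = {"cell_annotations": annot, "composition": comp}
    if profiles.shape[0] >= 2:
        link = cl.hierarchical_group(profiles)
        tables["cluster_dendrogram"] = pd.DataFrame(
            link, columns=["merge_a", "merge_b", "height", "n_members"])
    write_results(tables, _stage_dir(config, "cluster"),
                  config=config.semantic_dict(), seed=config.seed)
    state["annotations"] = annot
    log(f"cluster: {len(np.unique(labels))} clusters")
    return {"n_clusters": int(len(np.unique(labels)))}


def _stage_markers(config: RunConfig, state: dict, log) -> dict:
    counts = state["counts"]
    table = mk.find_markers(state["normalized"], state["labels"],
                            counts.gene_ids)
    top = mk.top_markers(table)
    write_results({"markers": table, "top_markers": top},
                  _stage_dir(config, "markers"),
                  config=config.semantic_dict(), seed=config.seed)
    log(f"markers: {len(table)} tests, {len(top)} top markers")
    return {"n_tests": int(len(table))}


def _stage_clonotype(config: RunConfig, state: dict, log) -> dict:
    if state.get("contig_path") is None:
        raise ConfigError("no contig table available for clonotype stage")
    counts = state["counts"]
    contigs = read_contigs(state["contig_path"])
    opts = dict(config.clonotype)
    assignment = ct.call_clonotypes(
        contigs, mode=opts.get("mode", "trb_only"),
        scope=opts.get("scope", "global"),
        conditions=dict(zip(counts.barcodes,
                            counts.conditions)) if opts.get("scope") ==
        "per_condition" else None)
    labels_map = dict(zip(counts.barcodes, state["labels"]))
    cond_map = dict(zip(counts.barcodes, counts.conditions))
    stats = ct.cluster_clonal_stats(assignment, labels_map, cond_map,
                                    size_scope=opts.get("size_scope", "global"))
    sharing = ct.clone_sharing(assignment, labels_map, cond_map)
    uniq = ct.count_unique_clones(assignment, cond_map).reset_index()
    sharing_rows = []
    for cond, entry in sharing.items():
        mat = entry["matrix"]
        for i in mat.index:
            for j in mat.columns:
                sharing_rows.append({"condition": cond, "cluster_i": i,
                                     "cluster_j": j,
                                     "pct_shared": mat.loc[i, j]})
    write_results({"clonal_stats": stats,
                   "clone_sharing": pd.DataFrame(sharing_rows),
                   "unique_clones": uniq,
                   "clone_assignment": assignment.frame()},
                  _stage_dir(config, "clonotype"),
                  config=config.semantic_dict(), seed=config.seed)
    state["assignment"] = assignment
    log(f"clonotype: {len(assignment.clone_keys)} clones, "
        f"{len(assignment.unassigned)} unassigned barcodes")
    return {"n_clones": len(assignment.clone_keys)}


def _stage_regulon(config: RunConfig, state: dict, log) -> dict:
    counts = state["counts"]
    opts = dict(config.regulon)
    tf_list = opts.get("tf_list")
    if tf_list is None and state.get("truth") is not None \
            and state["truth"].regulon_truth:
        tf_list = list(state["truth"].regulon_truth)
    if not tf_list:
        raise ConfigError("regulon stage needs a tf_list (or planted TFs)")
    regs = rg.build_regulons(state["normalized"], counts.gene_ids, tf_list,
                             n_top_targets=opts.get("n_top_targets", 20),
                             min_corr=opts.get("min_corr", 0.1))
    activity = rg.score_regulons(state["normalized"], counts.gene_ids, regs,
                                 top_fraction=opts.get("top_fraction", 0.05))
    diff_cluster = rg.differential_regulon(activity, state["labels"])
    diff_cond = rg.differential_regulon(activity,
                                        counts.conditions.to_numpy())
    act_table = activity.reset_index(names="regulon")
    write_results({"regulons": rg.regulons_to_frame(regs),
                   "regulon_activity": act_table,
                   "diff_regulon_cluster": diff_cluster,
                   "diff_regulon_condition": diff_cond},
                  _stage_dir(config, "regulon"),
                  config=config.semantic_dict(), seed=config.seed)
    state["regulons"] = regs
    log(f"regulon: {len(regs)} regulons scored")
    return {"n_regulons": len(regs)}


def _stage_gem(config: RunConfig, state: dict, log) -> dict:
    counts = state["counts"]
    opts = dict(config.gem)
    tree = gems.build_tree(tuple(opts.get("branching", gems.DEFAULT_BRANCHING)))
    priors = gems.NhdpPriors(eta=opts.get("eta", 0.1),
                             alpha_stop=opts.get("alpha_stop", 1.0),
                             alpha_branch=opts.get("alpha_branch", 1.0))
    node_dist, cell_gem, diag = gems.fit_nhdp(
        counts, tree, priors, n_iter=opts.get("n_iter", 200),
        burn_in=opts.get("burn_in", 100), seed=int(config.seed))
    ranked = []
    for n in range(tree.n_nodes):
        for rank, g in enumerate(gems.ranked_genes(
                node_dist, n, top_n=opts.get("top_n", 20))):
            ranked.append({"node_id": n, "rank": rank, "gene": g})
    diff = gems.gem_differential(
        cell_gem, counts.conditions.to_numpy(),
        gems.GemDifferentialConfig(alpha=opts.get("alpha", 0.05)))
    import scipy.sparse as sp
    write_results({"gem_tree": tree.table(),
                   "gem_ranked_genes": pd.DataFrame(ranked),
                   "gem_differential": diff,
                   "gem_diagnostics": diag},
                  _stage_dir(config, "gem"),
                  matrices={"cell_gem_counts": sp.csr_matrix(cell_gem.counts)},
                  config=config.semantic_dict(), seed=config.seed)
    state["cell_gem"] = cell_gem
    log(f"gem: {tree.n_nodes} nodes, {len(diff)} differential tests")
    return {"n_nodes": tree.n_nodes}


def _stage_report(config: RunConfig, state: dict, log) -> dict:
    path = Path(config.out_dir) / "report.md"
    doc = render_report(Path(config.out_dir))
    path.write_text(doc, encoding="utf-8")
    log("report rendered")
    return {"path": path.name}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "markers": _stage_markers,
    "clonotype": _stage_clonotype,
    "regulon": _stage_regulon,
    "gem": _stage_gem,
    "report": _stage_report,
}


def _read_tsv(path: Path) -> pd.DataFrame | None:
    return pd.read_csv(path, sep="\t") if path.exists() else None


def _section(title: str, df: pd.DataFrame | None, max_rows: int = 20) -> str:
    if df is None:
        return f"## {title}\n\nnot run\n"
    shown = df.head(max_rows)
    return f"## {title}\n\n```\n{shown.to_string(index=False)}\n```\n"


def render_report(run_dir) -> str:
    """Assemble the summary document from a completed run directory.

    Pure rendering: reads only the stage output files, so regenerating the
    report from the same directory is byte-identical.
    """
    run_dir = Path(run_dir)
    parts = ["# clonogem run report\n"]
    manifest_path = run_dir / "run_manifest.json"
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as fh:
            man = json.load(fh)
        parts.append(f"config hash `{man['config_hash']}`, "
                     f"seed {man['seed']}\n")
    parts.append(_section("Cluster composition by condition",
                          _read_tsv(run_dir / "cluster" / "composition.tsv")))
    parts.append(_section("Clonal statistics per cluster",
                          _read_tsv(run_dir / "clonotype" / "clonal_stats.tsv")))
    parts.append(_section("Clone sharing between clusters",
                          _read_tsv(run_dir / "clonotype" / "clone_sharing.tsv"),
                          max_rows=50))
    parts.append(_section("Top markers per cluster",
                          _read_tsv(run_dir / "markers" / "top_markers.tsv")))
    parts.append(_section("Differential regulons (per cluster)",
                          _read_tsv(run_dir / "regulon" /
                                    "diff_regulon_cluster.tsv")))
    parts.append(_section("Top GEM genes",
                          _read_tsv(run_dir / "gem" / "gem_ranked_genes.tsv"),
                          max_rows=30))
    parts.append(_section("Differential GEMs",
                          _read_tsv(run_dir / "gem" / "gem_differential.tsv")))
    return "\n".join(parts)
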