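"""End-to-end orchestration: curate -> differential -> chemometrics -> venn -> enrich -> diffuse.

A single config (YAML/JSON or a :class:`PipelineConfig`) drives the run.
Two input modes exist: file inputs (peak tables + run designs + pathway
sets + graph) or a self-contained synthetic study generated from the
config seed.  Every output carries the seed; the report is a plain JSON
document with per-stage audits and the key counts.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import yaml

from . import chemometrics, curation, differential, diffusion, enrichment, io, simulate, venn
from .model import KnowledgeGraph, Pathway, PathwayLibrary, ValidationError


@dataclass
class PipelineConfig:
    out_dir: str = "metabocurate_out"
    seed: int = 0
    alpha: float = 0.05
    pca_k: int = 2
    curation: curation.CurationConfig = field(default_factory=curation.CurationConfig)
    diffusion: diffusion.DiffusionConfig = field(default_factory=diffusion.DiffusionConfig)
    simulation: Optional[simulate.SimulationConfig] = None  # synthetic mode when set
    # file-input mode
    peaks: Optional[str] = None
    design: Optional[str] = None
    cse_peaks: Optional[str] = None
    cse_design: Optional[str] = None
    blanks: Optional[str] = None
    blanks_design: Optional[str] = None
    pathways_gmt: Optional[str] = None
    graph_nodes: Optional[str] = None
    graph_edges: Optional[str] = None


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "curation" in kwargs:
        kwargs["curation"] = curation.CurationConfig(**kwargs["curation"])
    if "diffusion" in kwargs:
        kwargs["diffusion"] = diffusion.DiffusionConfig(**kwargs["diffusion"])
    if "simulation" in kwargs and kwargs["simulation"] is not None:
        kwargs["simulation"] = simulate.SimulationConfig(**kwargs["simulation"])
    return PipelineConfig(**kwargs)


def study_library(truth: simulate.SyntheticTruth) -> PathwayLibrary:
    """Subclass-based pathway library over the synthetic compounds (ids = InChIKeys)."""
    pathways: dict[str, Pathway] = {}
    for pid, sub in truth.compounds.groupby("pathway"):
        pathways[pid] = Pathway(pid, pid.split(":", 1)[1], frozenset(sub.index))
    return PathwayLibrary(pathways)


def study_graph(truth: simulate.SyntheticTruth) -> KnowledgeGraph:
    """Layered toy knowledge graph for a synthetic study: pathway-module-enzyme-reaction-compounds."""
    g = nx.Graph()
    for pid, sub in truth.compounds.groupby("pathway"):
        tag = pid.split(":", 1)[1]
        chain = [(pid, "pathway"), (f"MD:{tag}", "module"), (f"EC:{tag}", "enzyme"), (f"RN:{tag}", "reaction")]
        for node, t in chain:
            g.add_node(node, node_type=t)
        for (a, _), (b, _) in zip(chain, chain[1:]):
            g.add_edge(a, b)
        for ik in sub.index:
            g.add_node(ik, node_type="compound")
            g.add_edge(f"RN:{tag}", ik)
    return KnowledgeGraph(g)


def _replicate_level_matrix(table, curated):
    """Imputed replicate-level matrix restricted to curated metabolites.

    Chemometrics runs on all injections (replicates included), while the
    differential statistics run on replicate-collapsed samples.
    """
    keep = set(curated.metabolite_ids)
    sub = table.subset_features([fid for fid in table.feature_ids if fid in keep])
    return curation.impute_half_lld(sub).values


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the JSON report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    t_start = time.perf_counter()

    def stage(name):
        # stage timings go to stderr only, keeping the report byte-deterministic
        print(f"[metabocurate] {name} done at {time.perf_counter() - t_start:.2f}s", file=sys.stderr)
        report["stages"][name] = {}
        return report["stages"][name]

    # ---- inputs -----------------------------------------------------------
    if cfg.simulation is not None or cfg.peaks is None:
        sim_cfg = cfg.simulation or simulate.SimulationConfig()
        sim_cfg = dataclasses.replace(sim_cfg, seed=cfg.seed)
        study = simulate.simulate_study(sim_cfg)
        plasma, cse_table, blank_table = study.plasma, study.cse, study.blanks
        library = study_library(study.truth)
        kg = study_graph(study.truth)
        report["input_mode"] = "synthetic"
    else:
        if not (cfg.design and cfg.blanks and cfg.blanks_design):
            raise ValidationError("file-input mode needs peaks, design, blanks, blanks_design")
        plasma = io.read_peak_table(cfg.peaks, cfg.design)
        blank_table = io.read_peak_table(cfg.blanks, cfg.blanks_design)
        cse_table = (
            io.read_peak_table(cfg.cse_peaks, cfg.cse_design)
            if cfg.cse_peaks and cfg.cse_design
            else None
        )
        library = io.read_pathway_sets(cfg.pathways_gmt) if cfg.pathways_gmt else None
        kg = (
            io.read_graph(cfg.graph_nodes, cfg.graph_edges)
            if cfg.graph_nodes and cfg.graph_edges
            else None
        )
        report["input_mode"] = "files"

    # ---- curation ---------------------------------------------------------
    curated = curation.curate(plasma, blank_table, cfg.curation)
    io.write_curated(curated, out / "curated.tsv")
    s = stage("curation")
    s["audit"] = {k: v for k, v in curated.audit.items() if k != "merged_groups"}
    s["n_metabolites"] = len(curated.metabolites)

    # ---- differential -----------------------------------------------------
    results, summary = differential.differential_table(curated, alpha=cfg.alpha)
    differential.results_frame(results).to_csv(out / "differential.tsv", sep="\t")
    subclasses = differential.subclass_fc(results, alpha=cfg.alpha)
    s = stage("differential")
    s["summary"] = summary
    s["significant_subclasses"] = sorted(
        sc.subclass for sc in subclasses if sc.significant
    )

    # ---- chemometrics -----------------------------------------------------
    scaled = chemometrics.scale_matrix(_replicate_level_matrix(plasma, curated))
    pca_res = chemometrics.pca(scaled, k=min(cfg.pca_k, min(scaled.shape) - 1) or 1)
    pca_res.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pca_res.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    dr = chemometrics.ward_cluster(scaled, axis="metabolites")
    dc = chemometrics.ward_cluster(scaled, axis="samples")
    chemometrics.heatmap_export(scaled, dr, dc, out / "heatmap.tsv")
    s = stage("chemometrics")
    s["bartlett_p"] = pca_res.bartlett_p
    s["variance_explained_pc1_pc2"] = float(pca_res.variance_explained[:2].sum())
    s["top_loadings"] = list(chemometrics.top_loadings(pca_res, top=10).index)

    # ---- venn / bioavailability ------------------------------------------
    if cse_table is not None:
        key_of = {f.feature_id: (f.inchikey or f.name) for f in curated.metabolites}
        basal = {key_of[fid] for fid in venn.detected_set(curated, "basal")}
        day7 = {key_of[fid] for fid in venn.detected_set(curated, "day7")}
        cse_set = {
            (f.inchikey or f.name)
            for f in cse_table.features
            if cse_table.intensity.loc[f.feature_id].notna().any()
        }
        part = venn.venn_partition(cse_set, basal, day7)
        bio = venn.classify_bioavailable(part)
        with open(out / "venn.json", "w") as fh:
            json.dump(venn.audit_percentages(part), fh, indent=2)
        s = stage("venn")
        s["bioavailable"] = sorted(bio)
        s["region_counts"] = {
            name: entry["count"] for name, entry in venn.audit_percentages(part)["regions"].items()
        }
    else:
        bio = frozenset()

    # ---- pathway enrichment ----------------------------------------------
    sig_keys = sorted(
        (r.metabolite.inchikey or r.metabolite.name) for r in results if r.significant
    )
    if library is not None and sig_keys:
        enr = enrichment.enrich_all(sig_keys, library, alpha=cfg.alpha)
        with open(out / "enrichment.tsv", "w") as fh:
            fh.write("pathway_id\tname\tk\tK\tn\tN\timpact\tp\tenrichment_ratio\tfdr\n")
            for r in enr:
                fh.write(
                    f"{r.pathway_id}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
                    f"\t{r.impact:.6g}\t{r.p:.6g}\t{r.enrichment_ratio:.6g}\t{r.q:.6g}\n"
                )
        s = stage("enrichment")
        s["top_pathways"] = [r.pathway_id for r in enr[:5]]
        s["n_significant_pathways"] = sum(1 for r in enr if r.q <= cfg.alpha)

    # ---- network diffusion -------------------------------------------------
    if kg is not None and sig_keys:
        dcfg = dataclasses.replace(cfg.diffusion, seed=cfg.seed)
        inputs = set(sig_keys) & set(kg.compounds)
        if inputs:
            dres = diffusion.diffuse(kg, inputs, dcfg)
            dres.table.to_csv(out / "diffusion.tsv", sep="\t")
            s = stage("diffusion")
            s["selected_pathways"] = dres.selected_pathways
            s["n_selected"] = int(dres.table["selected"].sum())

    print(f"[metabocurate] finished in {time.perf_counter() - t_start:.2f}s", file=sys.stderr)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
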