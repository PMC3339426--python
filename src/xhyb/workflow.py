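"""End-to-end workflow orchestration from a single config.

Two entry points: :func:`run_reannotation` composes the probe
re-annotation chain (hit filtering -> hybridization graph -> EST
translation -> ortholog clustering -> annotation projection -> probe
annotation), and :func:`run_full` continues through differential
expression, GO enrichment and cross-species co-expression.  Every stage
writes its intermediate next to the results, the resolved config is
serialized alongside, and a stage failure aborts with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from xhyb import coexpress, de, hybgraph, io, orthology
from xhyb.enrich import annotation_universe, enrich as enrich_terms, propagate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and tunables of a full workflow run.

    Every workflow parameter surfaces as a named key with its standard
    default: 80 % identity / 100 bp for hybridization edges, normexp
    offset 50, significance level 0.05, co-expression thresholds
    0.05/0.1/0.2.
    """

    # inputs
    probes_fasta: str | None = None
    ests_fasta: str | None = None
    hits_table: str | None = None
    protein_hits_table: str | None = None
    clusters_file: str | None = None
    reference_annotations: str | None = None
    gpr_files: list[str] = field(default_factory=list)
    targets_table: str | None = None
    obo_file: str | None = None
    compendium_matrix: str | None = None
    gene_to_probeset_hits: str | None = None
    # tunables
    min_identity: float = 80.0
    min_length: int = 100
    min_orf_aa: int = 30
    inflation: float = 1.5
    evalue_cutoff: float = 1e-5
    normexp_offset: float = 50.0
    loess_span: float = 0.3
    alpha: float = 0.05
    fdr_method: str = "bh"
    enrichment_adjust: str = "by"
    coexpression_thresholds: tuple[float, ...] = (0.05, 0.1, 0.2)
    linkage: str = "average"
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run_reannotation(config: RunConfig) -> dict:
    """Filter hits, build the graph, cluster, project, annotate probes.

    Returns a dict of in-memory results and writes the probe annotation
    table, graph exports and probe metrics to ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    probes = _stage("read_probes")(io.read_fasta)(config.probes_fasta)
    ests = _stage("read_ests")(io.read_fasta)(config.ests_fasta)
    hits = _stage("read_hits")(io.read_hit_table)(config.hits_table)

    @_stage("hybridization_graph")
    def build():
        edges = hybgraph.filter_hits(hits, config.min_identity,
                                     config.min_length)
        graph = hybgraph.build_graph(
            edges, isolated_probes=set(probes.ids),
            min_identity=config.min_identity, min_length=config.min_length)
        if not edges:
            logger.warning("no hits pass the hybridization thresholds; "
                           "all probes will be unannotated")
        return graph

    graph = build()

    @_stage("translate")
    def translate():
        return orthology.translate_ests(ests, min_orf_aa=config.min_orf_aa)

    proteins = translate()

    @_stage("cluster")
    def cluster():
        if config.clusters_file:
            return orthology.read_clusters(config.clusters_file)
        phits = io.read_hit_table(config.protein_hits_table)
        return orthology.cluster_orthologs(
            phits, inflation=config.inflation,
            evalue_cutoff=config.evalue_cutoff,
            all_proteins={pid for pid, *_ in proteins.records})

    clusters = cluster()

    @_stage("project")
    def project():
        ref = io.read_probe_annotation(config.reference_annotations)
        return orthology.project_annotations(clusters, ref)

    projected = project()

    @_stage("annotate_probes")
    def annotate():
        return orthology.annotate_probes(graph, projected,
                                         proteins.est_to_protein)

    probe_ann = annotate()

    metrics = hybgraph.probe_metrics(graph)
    io.write_probe_annotation(probe_ann, out / "probe_annotation.tsv")
    hybgraph.metrics_to_tsv(metrics, out / "probe_metrics.tsv")
    io.write_graph_xgmml(graph.graph, out / "hybridization_graph.xgmml")
    config.to_yaml(out / "config.resolved.yaml")
    return {"graph": graph, "proteins": proteins, "clusters": clusters,
            "projected": projected, "probe_annotation": probe_ann,
            "metrics": metrics}


def run_full(config: RunConfig) -> dict:
    """Re-annotation + DE + enrichment + co-expression, all written out."""
    out = Path(config.out_dir)
    results = run_reannotation(config)

    @_stage("differential_expression")
    def run_de():
        targets = pd.read_csv(config.targets_table, sep="\t")
        model = de.TwoColorDEModel.from_gpr_files(
            config.gpr_files, targets,
            params=de.NormalizationParams(
                normexp_offset=config.normexp_offset,
                loess_span=config.loess_span))
        return model.fit(alpha=config.alpha, fdr_method=config.fdr_method)

    de_results = run_de()
    de_results.to_tsv(out / "de_table.tsv")
    classification, counts = de_results.classify()
    counts.rename_axis("category").to_frame("probes").to_csv(
        out / "de_summary.tsv", sep="\t")

    @_stage("enrichment")
    def run_enrich():
        dag = io.read_obo(config.obo_file)
        propagated = propagate(dag, results["probe_annotation"])
        universe = annotation_universe(propagated)
        selected = set()
        for line in de_results.coef_names:
            selected |= set(de_results.significant(line))
        selected &= universe
        return enrich_terms(selected, universe, propagated,
                             adjust=config.enrichment_adjust)

    enrichment = run_enrich()
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    @_stage("coexpression")
    def run_coexpress():
        comp = coexpress.ExpressionCompendium.from_tsv(
            config.compendium_matrix)
        hits = io.read_hit_table(config.gene_to_probeset_hits)
        mapped, unmappable = coexpress.map_clusters(
            results["clusters"], hits, config.min_identity,
            config.min_length)
        probesets = sorted(set().union(*mapped.values())) if mapped else []
        vectors, missing = coexpress.expression_vectors(comp, probesets)
        groups = []
        if len(vectors) >= 2:
            r = coexpress.pearson_matrix(vectors)
            for thr in config.coexpression_thresholds:
                groups.append(coexpress.coexpressed_groups(
                    r, thr, linkage_method=config.linkage))
        return groups, unmappable, missing

    groups, unmappable, missing = run_coexpress()
    coexpress.groups_to_tsv(groups, out / "coexpression_groups.tsv")

    log = {
        "config_hash": config.config_hash(),
        "n_probes": len(results["probe_annotation"]),
        "n_clusters": len(results["clusters"]),
        "n_de_probes_total": int(counts["Total"]),
        "de_counts": {k: int(v) for k, v in counts.items()},
        "n_enriched_terms_tested": int(len(enrichment)),
        "unmappable_clusters": unmappable,
        "missing_probesets": missing,
        "duplicate_correlation": de_results.rho,
        "prior_df": de_results.d0,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    results.update({"de": de_results, "classification": classification,
                    "counts": counts, "enrichment": enrichment,
                    "coexpression": groups, "log": log})
    return results
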