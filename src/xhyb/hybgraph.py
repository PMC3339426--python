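"""Bipartite probe-transcript hybridization graph.

On a cross-species array a probe may hybridize to several transcripts of
the probed species, and several probes may report the same transcript.
Similarity hits between probe and transcript sequences are filtered at a
hybridization-plausibility threshold (>= 80 % identity over >= 100 bp by
default) and stored as a bipartite graph whose connected components group
probes that plausibly report the same underlying gene(s).  The component
count of a probe set therefore estimates how many genes that set monitors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

DEFAULT_MIN_IDENTITY = 80.0   # percent
DEFAULT_MIN_LENGTH = 100      # bp


@dataclass(frozen=True)
class HybEdge:
    """One retained probe-transcript hybridization prediction."""
    probe_id: str
    transcript_id: str
    percent_identity: float
    alignment_length: int
    bitscore: float = 0.0


@dataclass
class HybGraph:
    """Bipartite graph of probes and the transcripts they may hybridize to."""

    graph: nx.Graph
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_length: int = DEFAULT_MIN_LENGTH

    @property
    def probes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d.get("type") == "probe"}

    @property
    def transcripts(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d.get("type") == "transcript"}

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def __contains__(self, node):
        return node in self.graph


def filter_hits(hits: pd.DataFrame,
                min_identity: float = DEFAULT_MIN_IDENTITY,
                min_length: int = DEFAULT_MIN_LENGTH,
                probe_column: str = "subject_id",
                transcript_column: str = "query_id") -> set[HybEdge]:
    """Retain hits meeting the hybridization thresholds (inclusive).

    Duplicate (probe, transcript) pairs collapse to the single best edge
    (highest bitscore, then highest identity): the graph models whether
    hybridization is likely, not how many local alignments support it.
    """
    ok = hits[(hits["percent_identity"] >= min_identity)
              & (hits["alignment_length"] >= min_length)]
    best: dict[tuple[str, str], HybEdge] = {}
    for row in ok.itertuples(index=False):
        probe = getattr(row, probe_column)
        transcript = getattr(row, transcript_column)
        edge = HybEdge(probe, transcript, float(row.percent_identity),
                       int(row.alignment_length), float(row.bitscore))
        key = (probe, transcript)
        prev = best.get(key)
        if prev is None or (edge.bitscore, edge.percent_identity) > (
                prev.bitscore, prev.percent_identity):
            best[key] = edge
    return set(best.values())


def build_graph(edges: set[HybEdge],
                isolated_probes: set[str] | None = None,
                min_identity: float = DEFAULT_MIN_IDENTITY,
                min_length: int = DEFAULT_MIN_LENGTH) -> HybGraph:
    """Assemble the bipartite graph from filtered edges.

    Probes with no qualifying hit may be supplied via ``isolated_probes``;
    they stay in the graph as isolated nodes ("no predicted target")
    rather than being dropped.
    """
    g = nx.Graph()
    probe_ids = {e.probe_id for e in edges} | set(isolated_probes or ())
    transcript_ids = {e.transcript_id for e in edges}
    clash = probe_ids & transcript_ids
    if clash:
        raise ValueError(
            f"probe ids collide with transcript ids (namespacing required): "
            f"{sorted(clash)[:5]}")
    for p in probe_ids:
        g.add_node(p, type="probe")
    for t in transcript_ids:
        g.add_node(t, type="transcript")
    for e in edges:
        g.add_edge(e.probe_id, e.transcript_id,
                   percent_identity=e.percent_identity,
                   alignment_length=e.alignment_length,
                   bitscore=e.bitscore)
    return HybGraph(g, min_identity=min_identity, min_length=min_length)


def probe_metrics(hg: HybGraph) -> pd.DataFrame:
    """Per-probe ambiguity and redundancy.

    ambiguity(p): number of distinct transcripts predicted to hybridize
    to p.  redundancy_partners(p): number of other probes sharing at least
    one such transcript with p.  A probe with ambiguity 1 and no partners
    is labeled specific; an isolated probe has no predicted target.
    """
    rows = []
    for p in sorted(hg.probes):
        transcripts = hg.neighbors(p)
        partners = set()
        for t in transcripts:
            partners |= hg.neighbors(t)
        partners.discard(p)
        ambiguity = len(transcripts)
        if ambiguity == 0:
            label = "no predicted target"
        elif ambiguity == 1 and not partners:
            label = "specific"
        else:
            label = "ambiguous"
        rows.append((p, ambiguity, len(partners), label))
    return pd.DataFrame(
        rows, columns=["probe_id", "ambiguity", "redundancy_partners",
                       "label"])


@dataclass
class ComponentPartition:
    components: list[set[str]]
    component_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.component_of:
            self.component_of = {n: i for i, comp in enumerate(self.components)
                                 for n in comp}

    def __len__(self):
        return len(self.components)


def connected_components(hg: HybGraph) -> ComponentPartition:
    """Connected components, ordered by smallest contained node id."""
    comps = [set(c) for c in nx.connected_components(hg.graph)]
    comps.sort(key=lambda c: min(c))
    return ComponentPartition(comps)


def estimate_gene_count(hg: HybGraph, probes: set[str]) -> int:
    """Estimate how many genes a probe set monitors.

    The subgraph induced by the given probes, their adjacent transcripts
    and all edges among them is extracted; its connected-component count
    is the gene estimate.  Probes sharing a transcript collapse into one
    component; an isolated probe counts as a singleton.
    """
    unknown = set(probes) - hg.probes
    if unknown:
        raise KeyError(f"unknown probe id(s): {sorted(unknown)[:5]}")
    nodes = set(probes)
    for p in probes:
        nodes |= hg.neighbors(p)
    sub = hg.graph.subgraph(nodes)
    return nx.number_connected_components(sub)


def metrics_to_tsv(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, sep="\t", index=False)
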